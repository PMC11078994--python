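# Category x rule pairings that lint flags as implausible (warning only,
# never an error: a profile author may always keep such a pairing).
# A procedural/"how" or motivational/"why" concept under a "Forbidden" rule
# is rarely what the author meant (e.g. forbidding "ethical approval").
# Columns: wCategory <tab> rule
how	Forbidden
why	Forbidden
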