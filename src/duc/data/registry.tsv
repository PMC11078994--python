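# Bundled illustrative concept registry for Digital Use Conditions tooling.
# Columns: uri <tab> preferredLabel <tab> synonyms (pipe-joined) <tab> wCategory <tab> defaultRule
# DUO_0000007 ("Disease specific research") is a genuine GA4GH Data Use Ontology
# purl; the remaining DUO-prefixed identifiers are illustrative registry rows
# for testing and demonstration, not assertions about DUO releases.
# A row whose source concept is directional (a "No ..." modifier tag) carries the
# atomic root as preferredLabel and defaultRule "Forbidden".
http://purl.obolibrary.org/obo/DUO_0000007	Disease specific research	disease-specific research|DS	why	Permitted
http://purl.obolibrary.org/obo/DUO_0000042	General research use	GRU|general research	what	Permitted
http://purl.obolibrary.org/obo/DUO_0000006	Health or medical or biomedical research	HMB|biomedical research	why	Permitted
http://purl.obolibrary.org/obo/DUO_0000018	Use for profit purposes	commercial use|profit-based research	why	Permitted
http://purl.obolibrary.org/obo/DUO_0000022	Use in a geographic region	Country|geographical restriction	where	Permitted
http://purl.obolibrary.org/obo/DUO_0000025	Time limit on use	time limit|use time limit	when	Obligatory
http://purl.obolibrary.org/obo/DUO_0000021	Ethical approval	ethics approval required|IRB approval	how	Obligatory
http://purl.obolibrary.org/obo/DUO_0000026	Approved user	user specific restriction	who	Permitted
http://purl.obolibrary.org/obo/DUO_0000028	Institution approval	institution specific restriction	who	Obligatory
http://purl.obolibrary.org/obo/DUO_0000020	Collaboration	collaboration required	how	Obligatory
http://purl.obolibrary.org/obo/DUO_0000015	General methods use	no general methods use	what	Forbidden
http://purl.obolibrary.org/obo/DOID_1826	epilepsy	epilepsy syndrome	unknown
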