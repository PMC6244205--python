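# Known cis-element boxes screened for anther-enriched promoter activity.
# Editable: add one row per candidate box (name, IUPAC consensus).
# name	consensus
POLLEN1LELAT52	AGAAA
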