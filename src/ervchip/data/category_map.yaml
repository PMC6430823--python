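# Custom repeat categories for enrichment summaries.
# Resolution order: exact repName match, then repName prefix, then repClass,
# then the fallback. L1Md_F is analysed separately from the rest of LINE.
named:
  IAPA_MM-int: IAPA_MM-int
  IAPEz-int: IAPEz-int
  IAPLTR1a: IAPLTR1a
  L1Md_F: L1Md_F
prefix:
  IAP: IAP other
class:
  LINE: LINE
fallback: repName
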