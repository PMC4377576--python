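# Rheumatoid-arthritis gene symbols curated from an OMIM keyword search
CD244
HLA-DR1B
MHC2TA
NFKBIL1
PAD
SLC22A4
PTPN8
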