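gene	variant_class	alt_count	coverage	known_snp_id
KIT	SNV	14	53	rs121913517
PCDHB11	SNV	12	32
RNF146	deletion	24	52
OPLAH	SNV	10	29	rs200933200
TESK1	SNV	11	28
MYRF	SNV	10	32
SLC39A9	SNV	24	37
RRN3P1	SNV	8	37
ZNF407	SNV	17	53	rs368982407
LAMA5	SNV	10	34
DOPEY2	SNV	20	59
STS	SNV	21	25	rs373509256
MAGEB16	SNV	24	28
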