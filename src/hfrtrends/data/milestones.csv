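hfr_class,nomination_year,listing_year
Sum11PBDE,2005,2009
HBCDD,2008,2013
BDE209,2013,2017
SumDP,2019,2023
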