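currency,year,eur_per_unit
USD,2001,1.11674
USD,2002,1.06259
USD,2003,0.88417
USD,2004,0.80392
USD,2005,0.80379
USD,2006,0.79643
USD,2007,0.72966
USD,2008,0.67990
USD,2009,0.71695
USD,2010,0.75432
GBP,2001,1.60828
GBP,2002,1.59099
GBP,2003,1.44553
GBP,2004,1.47400
GBP,2005,1.46231
GBP,2006,1.46685
GBP,2007,1.46126
GBP,2008,1.25584
GBP,2009,1.12241
GBP,2010,1.16572
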