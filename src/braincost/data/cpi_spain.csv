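year,index
1999,100.0000
2000,103.5000
2001,106.3980
2002,110.2283
2003,113.6454
2004,117.1684
2005,121.1521
2006,125.5136
2007,129.0280
2008,134.3181
2009,134.0495
2010,136.7305
2011,140.8324
2012,144.2124
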