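# Synthetic consumer-price index fixture (smooth 2.5%/yr inflation,
# normalized so index[2012] = 100). Only index ratios enter the
# constant-dollar conversion; this is synthetic test plumbing, not CPI-U.
year,index
1990,58.0865
1991,59.5386
1992,61.0271
1993,62.5528
1994,64.1166
1995,65.7195
1996,67.3625
1997,69.0466
1998,70.7727
1999,72.5420
2000,74.3556
2001,76.2145
2002,78.1198
2003,80.0728
2004,82.0747
2005,84.1265
2006,86.2297
2007,88.3854
2008,90.5951
2009,92.8599
2010,95.1814
2011,97.5610
2012,100.0000
2013,102.5000
2014,105.0625
2015,107.6891
2016,110.3813
2017,113.1408
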