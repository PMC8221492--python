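year,total_ids,unique_ids,new_ids,within_season_n,within_season_pct,prior_year_n,prior_year_pct,any_prior_n,any_prior_pct
2004,79,41,41,38,48,,,,
2005,168,38,18,130,77,20,53,20,53
2006,230,68,33,163,70,27,40,35,51
2007,141,55,19,86,61,34,62,36,65
2008,148,75,32,73,49,28,37,43,57
2009,297,96,33,201,68,46,48,63,66
2010,252,85,21,167,66,54,64,64,75
2011,242,103,41,139,57,44,43,62,60
2012,239,100,19,139,58,50,50,81,81
2013,452,151,52,301,67,68,45,99,66
2014,750,164,43,586,78,97,59,121,74
2015,874,213,58,661,76,120,56,155,73
2016,615,181,28,434,71,133,73,153,85
2017,113,77,4,36,32,58,75,73,95
2018,240,103,5,137,57,50,49,98,95
2019,388,140,21,243,64,67,48,119,85
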