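group,group_type,diarrhoea_0_23m,pneumonia_0_23m,total_child,breast_cancer_f,ovarian_cancer_f,t2dm_f,total_maternal
East Asia and Pacific,region,13932,39680,53613,11898,5922,19964,37785
Europe and Central Asia,region,2132,5302,7434,3007,1877,2683,7567
Middle East and North Africa,region,6455,15272,21727,1801,606,5261,7668
Latin America and Caribbean,region,3938,10897,14835,4292,2092,11503,17887
North America,region,0,0,0,0,0,0,0
South Asia,region,66530,96350,162880,3444,1677,10791,15913
Sub-Saharan Africa,region,132828,202064,334892,2626,1471,8028,12125
High income,income,11,95,106,704,471,654,1829
Upper-middle-income,income,10928,33952,44879,15677,7619,29414,52711
Lower-middle-income,income,147999,233025,381024,9313,4763,25323,39399
Low income,income,66877,102493,169370,1374,791,2839,5004
Total,total,225815,369565,595379,27069,13644,58230,98943
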