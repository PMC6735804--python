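group,group_type,diarrhoea_0_23m,pneumonia_0_23m,obesity_child,breast_cancer_f,ovarian_cancer_f,t2dm_f
East Asia and Pacific,region,19533482,1058553,374405,54393,9905,389006
Europe and Central Asia,region,3514920,357835,69231,11016,3214,52077
Middle East and North Africa,region,12704537,716047,168568,8379,902,101441
Latin America and Caribbean,region,13160409,778792,134192,18254,3355,118363
North America,region,33571,64739,0,0,0,0
South Asia,region,56056468,3346020,74249,14051,2435,121620
Sub-Saharan Africa,region,60843179,2317553,154311,11711,1745,75009
High income,income,335534,86075,9362,3249,728,15719
Upper-middle-income,income,24816631,1706300,528011,68921,12696,494165
Lower-middle-income,income,99358380,5375448,356162,39297,7230,313822
Low income,income,41336021,1471716,81421,6337,902,33809
Total,total,165846566,8639539,974956,117804,21556,857515
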