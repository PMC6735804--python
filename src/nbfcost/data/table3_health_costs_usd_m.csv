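group,group_type,diarrhoea,pneumonia,t2dm,total
East Asia and Pacific,region,78.40,182.05,54.60,315.04
Europe and Central Asia,region,27.16,38.81,29.86,95.84
Middle East and North Africa,region,19.88,81.51,30.69,132.08
Latin America and Caribbean,region,48.30,128.67,59.99,236.96
North America,region,0.00,1.83,26.44,28.27
South Asia,region,5.43,128.38,33.59,167.41
Sub-Saharan Africa,region,17.02,135.44,18.76,171.21
High income,income,20.76,16.83,33.86,71.45
Upper-middle-income,income,149.10,308.56,146.79,604.46
Lower-middle-income,income,25.16,335.49,69.38,430.03
Low income,income,1.17,35.80,3.91,40.88
Total,total,196.19,696.69,253.94,1146.81
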