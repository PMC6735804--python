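group,group_type,child_mortality_default,child_mortality_conservative,child_mortality_optimistic,maternal_mortality_default,maternal_mortality_conservative,maternal_mortality_optimistic,cognitive_default,cognitive_conservative,cognitive_optimistic,total_default,total_conservative,total_optimistic,pct_gni_default,pct_gni_conservative,pct_gni_optimistic
East Asia and Pacific,region,10.39,2.71,49.67,0.66,0.55,0.80,74.76,19.46,357.66,86.12,23.04,408.45,0.59,0.16,2.78
Europe and Central Asia,region,1.35,0.35,6.38,0.25,0.21,0.29,14.76,3.86,70.15,16.27,4.37,76.71,0.42,0.11,1.97
Middle East and North Africa,region,3.76,0.98,17.99,0.03,0.03,0.04,18.65,4.85,89.38,22.57,5.98,107.54,0.91,0.24,4.32
Latin America and Caribbean,region,4.08,1.07,19.35,0.28,0.23,0.34,32.25,8.41,154.02,36.85,9.94,173.95,0.70,0.19,3.32
North America,region,0.00,0.00,0.00,0.00,0.00,0.00,114.94,29.87,551.37,114.97,29.90,551.40,0.63,0.16,3.04
South Asia,region,10.58,2.75,50.59,0.02,0.02,0.02,11.73,3.05,56.12,22.49,5.99,106.90,0.84,0.22,3.99
Sub-Saharan Africa,region,23.56,6.59,101.00,0.02,0.01,0.02,18.31,5.05,80.05,42.06,11.82,181.25,2.58,0.72,11.11
Low and middle income,income_combined,53.57,14.41,244.27,1.08,0.90,1.30,162.55,42.62,769.48,218.27,59.01,1016.13,0.83,0.22,3.86
High income,income,0.15,0.04,0.71,0.18,0.15,0.22,122.84,31.92,589.28,123.06,32.03,590.06,0.25,0.06,1.20
Upper-middle-income,income,14.44,3.81,67.79,0.95,0.80,1.16,114.07,29.74,544.54,130.07,34.95,614.10,0.65,0.17,3.07
Lower-middle-income,income,35.19,9.53,158.64,0.12,0.10,0.14,44.73,11.88,207.87,80.47,21.94,367.09,1.36,0.37,6.20
Low income,income,3.95,1.07,17.83,0.01,0.00,0.01,3.74,1.01,17.07,7.73,2.12,34.95,1.99,0.54,8.98
Total,total,53.72,14.45,244.99,1.26,1.06,1.52,285.39,74.55,1358.75,341.33,91.04,1606.19,0.70,0.19,3.29
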