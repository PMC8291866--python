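variant,stratum_var,stratum,k,n_cases,n_controls,model,or,ci_low,ci_high,p_heter,p
rs1333049,none,Total,33,20365,29413,allele,1.13,1.05,1.21,<0.001,0.001
rs1333049,none,Total,33,20365,29413,heterozygous,1.08,0.99,1.18,<0.001,0.076
rs1333049,none,Total,33,20365,29413,homozygous,1.29,1.11,1.49,<0.001,0.001
rs1333049,none,Total,33,20365,29413,dominant,1.14,1.03,1.27,<0.001,0.011
rs1333049,none,Total,33,20365,29413,recessive,1.21,1.10,1.34,<0.001,<0.001
rs1333049,ethnicity,West Asian,8,3921,4023,allele,1.25,1.07,1.45,0.005,0.005
rs1333049,ethnicity,West Asian,8,3921,4023,heterozygous,1.10,0.98,1.23,0.072,0.091
rs1333049,ethnicity,West Asian,8,3921,4023,homozygous,1.73,1.14,2.64,<0.001,0.011
rs1333049,ethnicity,West Asian,8,3921,4023,dominant,1.26,0.98,1.62,0.018,0.066
rs1333049,ethnicity,West Asian,8,3921,4023,recessive,1.52,1.14,2.01,0.002,0.004
rs1333049,ethnicity,Caucasian,10,6979,12696,allele,1.05,0.89,1.24,<0.001,0.575
rs1333049,ethnicity,Caucasian,10,6979,12696,heterozygous,1.01,0.82,1.25,<0.001,0.916
rs1333049,ethnicity,Caucasian,10,6979,12696,homozygous,1.10,0.79,1.53,<0.001,0.565
rs1333049,ethnicity,Caucasian,10,6979,12696,dominant,1.04,0.81,1.33,<0.001,0.743
rs1333049,ethnicity,Caucasian,10,6979,12696,recessive,1.10,0.89,1.35,<0.001,0.397
rs1333049,ethnicity,East Asian,14,9173,12371,allele,1.15,1.06,1.25,<0.001,0.001
rs1333049,ethnicity,East Asian,14,9173,12371,heterozygous,1.12,1.02,1.23,0.039,0.023
rs1333049,ethnicity,East Asian,14,9173,12371,homozygous,1.32,1.11,1.57,<0.001,0.001
rs1333049,ethnicity,East Asian,14,9173,12371,dominant,1.18,1.05,1.33,<0.001,0.005
rs1333049,ethnicity,East Asian,14,9173,12371,recessive,1.23,1.09,1.39,<0.001,0.001
rs1333049,ethnicity,African,1,292,323,allele,0.90,0.72,1.25,-,0.381
rs1333049,ethnicity,African,1,292,323,heterozygous,0.92,0.63,1.34,-,0.661
rs1333049,ethnicity,African,1,292,323,homozygous,0.83,0.54,1.28,-,0.395
rs1333049,ethnicity,African,1,292,323,dominant,0.89,0.62,1.26,-,0.501
rs1333049,ethnicity,African,1,292,323,recessive,0.87,0.61,1.25,-,0.465
rs1333049,control_source,HB,14,4510,5840,allele,1.07,0.96,1.20,<0.001,0.229
rs1333049,control_source,HB,14,4510,5840,heterozygous,1.03,0.88,1.21,0.008,0.696
rs1333049,control_source,HB,14,4510,5840,homozygous,1.20,0.92,1.57,<0.001,0.178
rs1333049,control_source,HB,14,4510,5840,dominant,1.07,0.90,1.27,<0.001,0.437
rs1333049,control_source,HB,14,4510,5840,recessive,1.15,0.95,1.39,<0.001,0.144
rs1333049,control_source,PB,17,14589,22338,allele,1.15,1.04,1.27,<0.001,0.006
rs1333049,control_source,PB,17,14589,22338,heterozygous,1.11,0.98,1.25,<0.001,0.092
rs1333049,control_source,PB,17,14589,22338,homozygous,1.32,1.08,1.60,<0.001,0.006
rs1333049,control_source,PB,17,14589,22338,dominant,1.17,1.02,1.35,<0.001,0.028
rs1333049,control_source,PB,17,14589,22338,recessive,1.23,1.08,1.39,<0.001,0.002
rs1333049,control_source,NA,2,1266,1235,allele,1.27,1.13,1.42,0.475,<0.001
rs1333049,control_source,NA,2,1266,1235,heterozygous,1.13,0.92,1.39,0.810,0.249
rs1333049,control_source,NA,2,1266,1235,homozygous,1.56,1.24,1.95,0.597,<0.001
rs1333049,control_source,NA,2,1266,1235,dominant,1.29,1.06,1.56,0.667,0.012
rs1333049,control_source,NA,2,1266,1235,recessive,1.43,1.20,1.69,0.585,<0.001
rs1333049,phenotype,CAD,22,13262,16209,allele,1.12,1.02,1.22,<0.001,0.013
rs1333049,phenotype,CAD,22,13262,16209,heterozygous,1.06,0.94,1.20,<0.001,0.307
rs1333049,phenotype,CAD,22,13262,16209,homozygous,1.26,1.05,1.51,<0.001,0.012
rs1333049,phenotype,CAD,22,13262,16209,dominant,1.12,0.98,1.29,<0.001,0.092
rs1333049,phenotype,CAD,22,13262,16209,recessive,1.20,1.08,1.34,<0.001,0.001
rs1333049,phenotype,MI,11,7103,13204,allele,1.15,1.01,1.30,<0.001,0.034
rs1333049,phenotype,MI,11,7103,13204,heterozygous,1.11,0.98,1.27,0.010,0.102
rs1333049,phenotype,MI,11,7103,13204,homozygous,1.35,1.02,1.77,<0.001,0.033
rs1333049,phenotype,MI,11,7103,13204,dominant,1.17,1.00,1.38,<0.001,0.055
rs1333049,phenotype,MI,11,7103,13204,recessive,1.25,1.01,1.53,<0.001,0.037
rs4977574,none,Total,17,15550,19460,allele,1.18,1.07,1.29,<0.001,0.001
rs4977574,none,Total,17,15550,19460,heterozygous,1.16,1.05,1.29,0.001,0.003
rs4977574,none,Total,17,15550,19460,homozygous,1.39,1.16,1.67,<0.001,<0.001
rs4977574,none,Total,17,15550,19460,dominant,1.24,1.09,1.40,<0.001,0.001
rs4977574,none,Total,17,15550,19460,recessive,1.26,1.10,1.44,<0.001,0.001
rs4977574,ethnicity,West Asian,4,4294,3528,allele,1.13,1.06,1.21,0.678,<0.001
rs4977574,ethnicity,West Asian,4,4294,3528,heterozygous,1.03,0.92,1.16,0.372,0.607
rs4977574,ethnicity,West Asian,4,4294,3528,homozygous,1.28,1.12,1.46,0.657,<0.001
rs4977574,ethnicity,West Asian,4,4294,3528,dominant,1.11,0.99,1.25,0.507,0.062
rs4977574,ethnicity,West Asian,4,4294,3528,recessive,1.24,1.12,1.38,0.445,<0.001
rs4977574,ethnicity,Caucasian,8,7392,12030,allele,1.18,1.00,1.40,<0.001,0.055
rs4977574,ethnicity,Caucasian,8,7392,12030,heterozygous,1.18,0.99,1.40,<0.001,0.071
rs4977574,ethnicity,Caucasian,8,7392,12030,homozygous,1.33,0.99,1.94,<0.001,0.061
rs4977574,ethnicity,Caucasian,8,7392,12030,dominant,1.25,0.99,1.56,<0.001,0.057
rs4977574,ethnicity,Caucasian,8,7392,12030,recessive,1.23,0.97,1.56,<0.001,0.083
rs4977574,ethnicity,East Asian,5,3864,3902,allele,1.21,1.03,1.43,<0.001,0.023
rs4977574,ethnicity,East Asian,5,3864,3902,heterozygous,1.22,1.10,1.37,0.633,<0.001
rs4977574,ethnicity,East Asian,5,3864,3902,homozygous,1.53,1.13,2.08,0.002,0.006
rs4977574,ethnicity,East Asian,5,3864,3902,dominant,1.31,1.18,1.45,0.137,<0.001
rs4977574,ethnicity,East Asian,5,3864,3902,recessive,1.29,0.97,1.72,<0.001,0.080
rs4977574,control_source,HB,7,2257,1892,allele,1.17,0.93,1.47,<0.001,0.178
rs4977574,control_source,HB,7,2257,1892,heterozygous,1.27,1.08,1.48,0.190,0.003
rs4977574,control_source,HB,7,2257,1892,homozygous,1.39,0.91,2.13,<0.001,0.124
rs4977574,control_source,HB,7,2257,1892,dominant,1.27,0.96,1.66,0.012,0.093
rs4977574,control_source,HB,7,2257,1892,recessive,1.23,0.87,1.74,<0.001,0.242
rs4977574,control_source,PB,10,13293,17568,allele,1.18,1.06,1.31,<0.001,0.002
rs4977574,control_source,PB,10,13293,17568,heterozygous,1.14,1.02,1.28,<0.001,0.027
rs4977574,control_source,PB,10,13293,17568,homozygous,1.38,1.12,1.70,<0.001,0.003
rs4977574,control_source,PB,10,13293,17568,dominant,1.22,1.05,1.40,<0.001,0.007
rs4977574,control_source,PB,10,13293,17568,recessive,1.27,1.09,1.47,<0.001,0.002
rs4977574,phenotype,CAD,9,5747,5660,allele,1.18,1.04,1.34,<0.001,0.013
rs4977574,phenotype,CAD,9,5747,5660,heterozygous,1.28,1.16,1.41,0.199,<0.001
rs4977574,phenotype,CAD,9,5747,5660,homozygous,1.43,1.13,1.82,0.001,0.004
rs4977574,phenotype,CAD,9,5747,5660,dominant,1.28,1.09,1.51,0.031,0.003
rs4977574,phenotype,CAD,9,5747,5660,recessive,1.28,1.04,1.57,<0.001,0.017
rs4977574,phenotype,MI,8,9803,13800,allele,1.18,1.03,1.35,<0.001,0.016
rs4977574,phenotype,MI,8,9803,13800,heterozygous,1.14,0.99,1.31,0.001,0.065
rs4977574,phenotype,MI,8,9803,13800,homozygous,1.38,1.06,1.79,<0.001,0.018
rs4977574,phenotype,MI,8,9803,13800,dominant,1.22,1.03,1.45,<0.001,0.025
rs4977574,phenotype,MI,8,9803,13800,recessive,1.27,1.02,1.50,<0.001,0.028
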