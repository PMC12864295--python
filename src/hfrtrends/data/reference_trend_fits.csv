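hfr_class,waterbody,region,colony,n_years,fit_type,breakpoint_failed,psi,psi_se,slope_before,se_before,slope_after,se_after,t_value,p_value,label
HBCDD,Arctic,Arctic,East Bay,9,linear,True,,,0.01,0.05,,,0.27,0.79,
HBCDD,Arctic,Arctic,Great Slave Lake,6,linear,True,,,-0.09,0.04,,,2.30,0.08,
HBCDD,Atlantic,Atlantic,Gull Is,11,segmented,False,2011,0.79,0.79,0.28,-0.07,0.06,2.86,0.025,NI
HBCDD,Atlantic,Atlantic,Kent Is,10,linear,False,,,-0.08,0.03,,,-2.74,0.026,CT
HBCDD,Lake Erie,GreatLakesNiagara,Middle Is,15,segmented,False,2015,1.53,0.16,0.10,-0.21,0.07,1.54,0.15,
HBCDD,Lake Erie,GreatLakesNiagara,Port Colborne,14,segmented,False,2010,1.26,1.49,1.09,-0.04,0.13,1.36,0.20,
HBCDD,Lake Huron,GreatLakesNiagara,Chantry Is,14,segmented,False,2010,1.36,0.55,0.54,-0.09,0.028,1.02,0.33,
HBCDD,Lake Huron,GreatLakesNiagara,Double Is,14,segmented,False,2013,5.16,-0.20,0.36,0.07,0.12,-0.54,0.60,
HBCDD,Lake Ontario,GreatLakesNiagara,Hamilton H,14,segmented,False,2009,1.22,0.71,0.89,0.004,0.05,0.79,0.45,
HBCDD,Lake Ontario,GreatLakesNiagara,Snake Is,15,segmented,False,2010,1.11,1.67,1.12,-0.14,0.12,1.49,0.17,
HBCDD,Lake Ontario,GreatLakesNiagara,Toronto H,13,segmented,False,2012,4.01,-0.23,0.52,0.16,0.14,-0.46,0.66,
HBCDD,Lake Superior,GreatLakesNiagara,Agawa Rocks,15,segmented,False,2018,1.71,0.04,0.03,-0.17,0.09,1.34,0.21,
HBCDD,Lake Superior,GreatLakesNiagara,Granite Is,16,segmented,False,2013,6.80,-0.10,0.39,0.12,0.12,-0.25,0.81,
HBCDD,Niagara R,GreatLakesNiagara,Weseloh Rocks,10,segmented,False,2010,1.24,0.72,0.65,-0.13,0.05,-1.12,0.31,
HBCDD,St. Lawrence R,StLawrence,Ile Bellechasse,10,segmented,False,2011,1.15,0.62,0.38,-0.15,0.05,1.65,0.15,
HBCDD,St. Lawrence R,StLawrence,Ile Deslauriers,9,segmented,False,2011,5.96,0.20,0.64,-0.06,0.08,0.31,0.77,
HBCDD,St. Lawrence R,StLawrence,Strachan Is,14,linear,False,,,-0.06,0.03,,,-2.26,0.043,CT
Sum11PBDE,Arctic,Arctic,East Bay,9,linear,True,,,0.03,0.02,,,1.53,0.17,
Sum11PBDE,Arctic,Arctic,Great Slave Lake,6,segmented,False,2015,2.37,-0.17,0.18,0.30,0.19,-0.98,0.43,
Sum11PBDE,Atlantic,Atlantic,Gull Is,11,segmented,False,2018,5.24,-0.05,0.03,0.04,0.09,-1.41,0.20,
Sum11PBDE,Atlantic,Atlantic,Kent Is,10,segmented,False,2021,2.33,-0.12,0.04,0.20,0.55,-3.08,0.022,IT
Sum11PBDE,Lake Erie,GreatLakesNiagara,Middle Is,15,segmented,False,2018,3.73,0.02,0.03,-0.05,0.06,0.79,0.45,
Sum11PBDE,Lake Erie,GreatLakesNiagara,Port Colborne,14,segmented,False,2019,5.61,0.05,0.02,-0.21,0.42,2.03,0.07,
Sum11PBDE,Lake Huron,GreatLakesNiagara,Chantry Is,14,segmented,False,2011,2.27,0.13,0.16,-0.05,0.03,0.81,0.44,
Sum11PBDE,Lake Huron,GreatLakesNiagara,Double Is,14,segmented,False,2019,12.55,0.05,0.02,-0.05,0.38,2.34,0.042,LI
Sum11PBDE,Lake Ontario,GreatLakesNiagara,Hamilton H,14,segmented,False,2015,2.75,0.04,0.04,-0.05,0.03,0.87,0.40,
Sum11PBDE,Lake Ontario,GreatLakesNiagara,Snake Is,15,linear,True,,,-0.03,0.02,,,-2.22,0.045,CT
Sum11PBDE,Lake Ontario,GreatLakesNiagara,Toronto H,13,segmented,False,2014,2.78,-0.09,0.08,0.05,0.06,-1.05,0.32,
Sum11PBDE,Lake Superior,GreatLakesNiagara,Agawa Rocks,15,segmented,False,2018,6.84,0.03,0.04,-0.05,0.13,0.68,0.51,
Sum11PBDE,Lake Superior,GreatLakesNiagara,Granite Is,16,segmented,False,2015,1.04,0.07,0.02,-0.06,0.02,3.43,0.0050,LI
Sum11PBDE,Niagara R,GreatLakesNiagara,Weseloh Rocks,10,segmented,False,2013,6.93,0.004,0.074,0.05,0.05,0.06,0.96,
Sum11PBDE,St. Lawrence R,StLawrence,Ile Bellechasse,11,linear,False,,,-0.09,0.03,,,-3.50,0.0068,CT
Sum11PBDE,St. Lawrence R,StLawrence,Ile Deslauriers,10,segmented,False,2022,0.97,0.02,0.03,-0.47,0.39,0.67,0.53,
Sum11PBDE,St. Lawrence R,StLawrence,Strachan Is,14,linear,False,,,-0.05,0.01,,,-6.02,0.000060,CT
BDE209,Arctic,Arctic,East Bay,8,segmented,False,2013,2.24,0.22,0.30,-0.10,0.05,0.72,0.50,
BDE209,Arctic,Arctic,Great Slave Lake,6,segmented,False,2016,0.84,-0.42,0.09,0.23,0.09,-4.81,0.041,IT
BDE209,Atlantic,Atlantic,Gull Is,11,segmented,False,2017,7.99,-0.02,0.06,0.04,0.08,-0.40,0.70,
BDE209,Atlantic,Atlantic,Kent Is,10,linear,False,,,-0.07,0.03,,,-2.43,0.039,CT
BDE209,Lake Erie,GreatLakesNiagara,Middle Is,15,segmented,False,2015,4.26,0.06,0.11,-0.12,0.11,0.51,0.62,
BDE209,Lake Erie,GreatLakesNiagara,Port Colborne,14,segmented,False,2015,1.89,0.19,0.11,-0.19,0.11,1.71,0.12,
BDE209,Lake Huron,GreatLakesNiagara,Chantry Is,14,segmented,False,2016,2.80,0.04,0.06,-0.10,0.06,0.70,0.50,
BDE209,Lake Huron,GreatLakesNiagara,Double Is,14,segmented,False,2016,3.50,0.10,0.07,-0.06,0.10,1.45,0.18,
BDE209,Lake Ontario,GreatLakesNiagara,Hamilton H,14,segmented,False,2015,3.58,0.11,0.10,-0.07,0.11,1.14,0.28,
BDE209,Lake Ontario,GreatLakesNiagara,Snake Is,15,segmented,False,2015,3.12,0.30,0.17,-0.06,0.17,1.76,0.11,
BDE209,Lake Ontario,GreatLakesNiagara,Toronto H,13,segmented,False,2016,2.12,0.02,0.07,-0.22,0.12,0.23,0.83,
BDE209,Lake Superior,GreatLakesNiagara,Agawa Rocks,15,segmented,False,2015,2.64,0.08,0.07,-0.10,0.07,1.04,0.32,
BDE209,Lake Superior,GreatLakesNiagara,Granite Is,16,segmented,False,2014,6.56,0.09,0.16,-0.03,0.11,0.58,0.57,
BDE209,Niagara R,GreatLakesNiagara,Weseloh Rocks,10,segmented,False,2011,1.44,-0.67,0.56,0.24,0.11,1.20,0.28,
BDE209,St. Lawrence R,StLawrence,Ile Bellechasse,11,linear,True,,,-0.11,0.02,,,-5.47,0.00040,CT
BDE209,St. Lawrence R,StLawrence,Ile Deslauriers,10,segmented,False,2010,0.44,-0.95,0.26,0.07,0.03,-3.59,0.0115,IT
BDE209,St. Lawrence R,StLawrence,Strachan Is,14,linear,False,,,0.12,0.04,,,3.30,0.0063,CT
SumDP,Arctic,Arctic,East Bay,8,segmented,False,2013,1.29,0.33,0.16,-0.06,0.05,2.05,0.10,
SumDP,Arctic,Arctic,Great Slave Lake,6,segmented,False,2015,2.60,-0.53,0.46,0.28,0.13,-1.14,0.37,
SumDP,Atlantic,Atlantic,Gull Is,10,segmented,False,2011,1.61,0.48,0.44,-0.15,0.05,1.09,0.31,
SumDP,Atlantic,Atlantic,Kent Is,9,segmented,False,2019,3.15,-0.16,0.14,0.28,0.34,-1.21,0.27,
SumDP,Lake Erie,GreatLakesNiagara,Middle Is,15,segmented,False,2014,1.71,0.53,0.30,-0.40,0.20,1.77,0.11,
SumDP,Lake Erie,GreatLakesNiagara,Port Colborne,14,segmented,False,2015,3.63,0.24,0.20,-0.12,0.21,1.20,0.26,
SumDP,Lake Huron,GreatLakesNiagara,Chantry Is,14,segmented,False,2011,2.62,0.17,0.29,-0.08,0.03,0.60,0.57,
SumDP,Lake Huron,GreatLakesNiagara,Double Is,14,segmented,False,2014,1.19,0.33,0.14,-0.21,0.07,2.37,0.039,EI
SumDP,Lake Ontario,GreatLakesNiagara,Hamilton H,14,linear,True,,,-0.10,0.04,,,-2.41,0.033,CT
SumDP,Lake Ontario,GreatLakesNiagara,Snake Is,15,segmented,False,2015,2.26,0.39,0.28,-0.28,0.19,1.41,0.19,
SumDP,Lake Ontario,GreatLakesNiagara,Toronto H,13,segmented,False,2012,1.32,0.23,0.16,-0.12,0.04,1.42,0.19,
SumDP,Lake Superior,GreatLakesNiagara,Agawa Rocks,15,segmented,False,2015,2.28,0.09,0.11,-0.18,0.08,0.82,0.43,
SumDP,Lake Superior,GreatLakesNiagara,Granite Is,16,linear,False,,,-0.08,0.03,,,-2.50,0.026,CT
SumDP,Niagara R,GreatLakesNiagara,Weseloh Rocks,10,segmented,False,2010,1.23,0.43,0.35,-0.09,0.07,1.25,0.26,
SumDP,St. Lawrence R,StLawrence,Ile Bellechasse,11,segmented,False,2013,1.36,0.37,0.17,-0.29,0.10,2.19,0.06,
SumDP,St. Lawrence R,StLawrence,Ile Deslauriers,10,segmented,False,2017,1.82,0.13,0.09,-0.25,0.10,1.40,0.21,
SumDP,St. Lawrence R,StLawrence,Strachan Is,14,segmented,False,2019,1.99,-0.07,0.05,0.29,0.19,1.33,0.21,
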