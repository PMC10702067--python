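trait,family,WW,YY,WY,YW,H_pct_WY_printed,H_pct_YW_printed,recip_pct_printed,sig_WY,sig_YW,sig_recip
FEWt,egg_weight,44.97,40.55,43.20,44.95,1.0,5.1,-4.1,,**,
EWt28,egg_weight,55.63,45.52,51.53,52.85,1.9,4.5,-2.6,**,**,
EWt32,egg_weight,57.01,48.06,53.84,54.61,2.5,4.0,-1.5,**,**,
EWt36,egg_weight,58.25,49.33,54.96,56.15,2.2,4.4,-2.2,**,**,
EWt40,egg_weight,59.34,50.52,56.39,57.42,2.7,4.5,-1.9,**,**,
EWt44,egg_weight,59.80,51.47,56.98,58.26,2.4,4.7,-2.3,**,**,
EWt48,egg_weight,60.74,52.87,58.35,59.75,2.7,5.2,-2.5,**,**,
EWt52,egg_weight,60.39,53.21,58.37,60.04,2.8,5.7,-2.9,**,**,
EWt56,egg_weight,60.81,54.58,59.30,61.26,2.8,6.2,-3.4,**,**,
EWt60,egg_weight,62.41,55.90,60.90,62.55,3.0,5.7,-2.8,**,**,
EWt64,egg_weight,62.23,56.26,61.18,62.81,3.3,6.0,-2.8,**,**,
EWt68,egg_weight,62.01,56.34,61.42,62.98,3.8,6.4,-2.6,**,**,
EWt72,egg_weight,61.24,55.92,60.95,62.52,4.0,6.7,-2.7,**,**,
EWt76,egg_weight,62.17,56.73,62.33,63.41,4.8,6.7,-1.8,**,**,
EWt86,egg_weight,60.87,56.93,62.25,63.17,5.7,7.2,-1.6,**,**,
EWt100,egg_weight,61.85,57.82,62.80,65.20,4.9,9.0,-4.0,**,**,
AFE,production,157.69,180.70,165.80,167.02,-2.0,-1.3,-0.7,**,*,
OP,production,24.31,26.21,25.11,25.29,-0.6,0.1,-0.7,,,
EN43,production,129.03,92.06,113.29,112.14,2.5,1.4,1.0,*,,
NC43,production,11.76,23.62,18.16,18.67,2.7,5.6,-2.9,,,
ACL43,production,14.16,3.95,6.79,6.45,-25.0,-28.8,3.8,**,**,
APL43,production,1.30,1.26,1.24,1.22,-3.1,-4.9,1.7,,,
EN72,production,280.65,201.23,253.34,247.39,5.1,2.7,2.5,**,*,
NC72,production,33.18,70.86,53.06,51.31,2.0,-1.4,3.4,,,
ACL72,production,9.72,2.89,4.98,4.90,-21.1,-22.2,1.1,**,**,
APL72,production,1.59,1.88,1.47,1.52,-15.3,-12.6,-2.7,*,,
EN100,production,379.91,270.33,362.67,352.77,11.6,8.5,3.0,**,**,
NC100,production,59.83,110.21,94.83,90.23,11.5,6.1,5.4,**,*,
ACL100,production,6.75,2.50,3.97,3.93,-14.2,-15.1,0.9,**,**,
APL100,production,2.57,2.41,1.88,1.93,-24.6,-22.3,-2.3,**,**,
ESI32,quality,75.09,78.02,76.04,76.21,-0.7,-0.4,-0.2,*,,
ESC32,quality,79.25,46.68,68.11,66.49,8.2,5.6,2.6,**,**,
ESS32,quality,3.29,3.95,3.80,4.00,4.8,10.3,-5.5,**,**,
EST32,quality,0.33,0.33,0.34,0.34,0.8,2.7,-1.9,,**,
ESR32,quality,9.63,10.07,9.97,10.10,1.2,2.5,-1.3,,**,
YR32,quality,26.56,30.64,29.16,29.22,1.9,2.2,-0.2,**,**,
YC32,quality,5.68,6.06,6.14,5.78,4.6,-1.5,6.1,**,,
HU32,quality,69.48,66.66,66.24,65.79,-2.7,-3.3,0.6,**,**,
ESI54,quality,73.36,74.28,73.42,73.36,-0.5,-0.6,0.1,,,
ESC54,quality,78.68,49.06,68.89,66.38,7.9,3.9,3.9,**,**,
ESS54,quality,3.08,3.75,3.44,3.84,0.9,12.6,-11.7,,**,*
EST54,quality,0.33,0.33,0.33,0.35,0.6,4.7,-4.1,,**,
ESR54,quality,9.00,9.36,9.22,9.45,0.5,2.9,-2.4,,**,
YR54,quality,28.21,32.24,30.65,30.81,1.4,1.9,-0.5,*,**,
YC54,quality,4.30,5.07,4.77,4.66,1.9,-0.4,2.3,,,
HU54,quality,78.60,74.86,73.68,74.56,-4.0,-2.8,-1.2,**,**,
ESI72,quality,72.79,73.60,73.18,73.13,-0.01,-0.1,0.1,,,
ESC72,quality,73.67,45.33,63.55,62.84,6.8,5.6,1.2,**,**,
ESS72,quality,2.92,3.63,3.39,3.65,3.6,11.4,-7.8,,**,
EST72,quality,0.31,0.31,0.32,0.33,4.1,6.6,-2.4,**,**,
ESR72,quality,8.80,9.06,9.16,9.28,2.6,3.9,-1.3,**,**,
YR72,quality,28.61,32.70,30.64,30.88,-0.04,0.7,-0.8,,,
YC72,quality,6.31,7.29,6.72,6.76,-1.2,-0.6,-0.6,,,
HU72,quality,76.25,73.76,70.78,72.90,-5.6,-2.8,-2.8,**,,
ESI86,quality,72.23,72.62,72.72,72.89,0.4,0.6,-0.2,,,
ESC86,quality,69.28,44.75,62.42,60.98,9.5,7.0,2.5,**,**,
ESS86,quality,2.78,3.47,3.19,3.32,2.2,6.3,-4.1,,*,
EST86,quality,0.33,0.33,0.34,0.35,3.3,5.9,-2.6,**,**,
ESR86,quality,8.50,8.74,8.81,8.93,2.2,3.6,-1.4,*,**,
YR86,quality,29.07,32.64,30.76,31.21,-0.3,1.1,-1.4,,,
YC86,quality,5.97,6.95,6.13,6.34,-5.1,-1.8,-3.3,,,
HU86,quality,70.53,69.49,63.91,66.51,-8.7,-5.0,-3.7,**,**,
ESI100,quality,72.67,73.33,72.74,72.40,-0.4,-0.8,0.5,,,
ESC100,quality,66.24,41.33,58.95,57.37,9.6,6.7,2.9,**,**,
ESS100,quality,2.71,3.05,2.97,2.91,3.0,1.1,2.0,,,
EST100,quality,0.30,0.29,0.29,0.30,0.2,4.2,-4.0,,**,
ESR100,quality,7.89,8.04,8.12,8.04,1.9,1.0,1.0,,,
YR100,quality,28.57,32.05,30.80,30.99,1.6,2.2,-0.6,,*,
YC100,quality,5.17,6.41,5.84,6.15,0.7,6.1,-5.4,,,
HU100,quality,68.16,67.66,61.25,64.49,-9.8,-5.0,-4.8,**,**,
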