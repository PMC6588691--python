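locus,panels,copies,k_single,k_multi,meioses,val_single,ci_low_single,ci_high_single,val_multi,ci_low_multi,ci_high_multi
DYS19,Yf/PP/YfP/L,1,3,3,1166,2.57,0.00,6.00,2.57,0.00,6.00
DYS389I,Yf/PP/YfP/L,1,3,3,1166,2.57,0.00,6.00,2.57,0.00,6.00
DYS389II-I,Yf/PP/YfP/L,1,3,3,1166,2.57,0.00,6.00,2.57,0.00,6.00
DYS390,Yf/PP/YfP/L,1,5,5,1166,4.29,0.86,8.58,4.29,0.86,8.58
DYS391,Yf/PP/YfP/L,1,2,2,1166,1.72,0.00,4.29,1.72,0.00,4.29
DYS392,Yf/PP/YfP/L,1,3,6,1166,2.57,0.00,6.00,5.15,1.72,9.43
DYS393,Yf/PP/YfP/L,1,3,3,1166,2.57,0.00,6.00,2.57,0.00,6.00
DYS385,Yf/PP/YfP/L,2,8,8,1166,6.86,2.57,12.01,6.86,2.57,12.01
DYS437,Yf/PP/YfP/L,1,4,4,1166,3.43,0.86,6.86,3.43,0.86,6.86
DYS438,Yf/PP/YfP/L,1,0,0,1166,,,,,,
DYS439,Yf/PP/YfP/L,1,7,9,1166,6.00,1.72,11.15,7.72,3.43,12.86
DYS448,Yf/PP/YfP/L,1,2,2,1166,1.72,0.00,4.29,1.72,0.00,4.29
DYS456,Yf/PP/YfP/L,1,3,3,1166,2.57,0.00,6.00,2.57,0.00,6.00
DYS458,Yf/PP/YfP/L,1,12,13,1166,10.29,5.15,16.30,11.15,5.15,17.15
DYS635,Yf/PP/YfP/L,1,2,2,1166,1.72,0.00,4.29,1.72,0.00,4.29
GATA H4.1,Yf/PP/YfP/L,1,3,3,1166,2.57,0.00,6.00,2.57,0.00,6.00
DYS481,PP/YfP/L,1,3,3,810,3.70,0.00,8.64,3.70,0.00,8.64
DYS533,PP/YfP/L,1,3,3,810,3.70,0.00,8.64,3.70,0.00,8.64
DYS570,PP/YfP/RM/L,1,9,9,1166,7.72,3.43,12.86,7.72,3.43,12.86
DYS576,PP/YfP/RM/L,1,10,11,1166,8.58,3.43,14.58,9.43,4.29,15.44
DYS549,PP/L,1,8,8,810,9.88,3.70,17.28,9.88,3.70,17.28
DYS643,PP/L,1,0,0,810,,,,,,
DYS460,YfP/L,1,1,1,718,1.39,0.00,4.18,1.39,0.00,4.18
DYS518,YfP/RM/L,1,18,18,1166,15.44,8.58,23.16,15.44,8.58,23.16
DYS627,YfP/RM/L,1,17,19,1166,14.58,7.72,21.44,16.30,9.43,24.01
DYF387S1,YfP/RM/L,2,13,13,1166,11.15,5.15,17.15,11.15,5.15,17.15
DYS449,YfP/RM/L,1,9,9,1166,7.72,3.43,12.86,7.72,3.43,12.86
DYS459,L,2,0,0,718,,,,,,
DYS724,L,2,25,29,718,34.82,22.28,48.75,40.39,26.46,55.71
DYS607,L,1,0,0,718,,,,,,
DYS455,L,1,0,0,718,,,,,,
DYS426,L,1,1,1,718,1.39,0.00,4.18,1.39,0.00,4.18
DYS454,L,1,0,0,718,,,,,,
DYS447,L,1,3,3,718,4.18,0.00,9.75,4.18,0.00,9.75
DYS442,L,1,2,2,718,2.79,0.00,6.96,2.79,0.00,6.96
DYS464,L,4,17,23,718,23.68,13.93,34.82,32.03,19.50,45.96
YCAII,L,2,0,0,718,,,,,,
DYS388,L,1,0,0,718,,,,,,
DYF399S1,RM,3,70,74,1149,60.92,47.87,74.85,64.40,50.48,79.20
DYS526A,RM,1,1,1,1166,0.86,0.00,2.57,0.86,0.00,2.57
DYS626,RM,1,9,10,1166,7.72,3.43,12.86,8.58,3.43,14.58
DYS526B,RM,1,5,6,1166,4.29,0.86,8.58,5.15,1.72,9.43
DYS612,RM,1,16,19,1166,13.72,7.72,20.58,16.30,9.43,24.01
DYS547,RM,1,15,16,1166,12.86,6.86,19.73,13.72,7.72,20.58
DYF404S1,RM,2,14,17,1166,12.01,6.00,18.87,14.58,7.72,21.44
DYF403S1a,RM,3,29,29,1152,25.17,16.49,34.72,25.17,16.49,34.72
DYF403S1b,RM,1,4,5,1166,3.43,0.86,6.86,4.29,0.86,8.58
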