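panel,k_single,k_multi,meioses,val_single,ci_low_single,ci_high_single,val_multi,ci_low_multi,ci_high_multi
Yf,63,69,18656,3.38,2.57,4.23,3.70,2.84,4.61
PP,96,103,24228,3.96,3.18,4.79,4.25,3.47,5.08
YfP,146,155,27990,5.22,4.39,6.07,5.54,4.68,6.43
L,202,221,37508,5.39,4.67,6.13,5.89,5.12,6.69
RM,239,256,17459,13.69,11.97,15.46,14.66,12.89,16.50
All,365,398,47971,7.61,6.84,8.40,8.30,7.50,9.11
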