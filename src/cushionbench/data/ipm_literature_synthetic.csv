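label,mean_mmHg,sd_mmHg,n
cushion_01,52.0,7.504,8
cushion_02,61.5,9.0694,6
cushion_03,48.3,9.6107,9
cushion_04,70.2,11.3725,5
cushion_05,55.8,11.2984,7
cushion_06,64.0,14.5924,8
cushion_07,58.6,12.4499,6
cushion_08,45.9,11.4624,7
cushion_09,67.3,18.8401,6
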