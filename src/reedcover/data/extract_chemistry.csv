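sample_id,pH,conductivity_mS_cm,soluble_salts_g_L
1,4.98,5.63,3.24
2,4.94,2.69,4.70
3,4.91,2.31,4.07
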