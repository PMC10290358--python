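analyte,lo,hi,units,note
pH,4.91,4.98,pH units,
soluble_salts,3.24,4.70,g/L,
total_nitrogen,32.4,39.6,g/L,
nitrate,5.63,7.83,g/L,source prints the range in descending order (7.83-5.63)
nitrite,0.035,0.058,g/L,source prints the range in descending order (0.058-0.035)
sulphate,87.7,99.8,g/L,
sulphide,0.012,0.025,g/L,
phosphate,3.45,3.66,g/L,
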