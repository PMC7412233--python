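# Manual-annotation benchmark of R-peak detection on ten 20-minute murine
# ECG fragments (lead II, down-sampled to 1000 Hz; 1,200,000 samples per
# fragment), as published for a custom murine AECG detector compared with
# the PhysioZoo platform.  Counts are sample-level TP/TN/FP/FN against
# manually annotated reference peaks.  Note: the published TN column of the
# PhysioZoo rows is internally inconsistent with the 1,200,000-sample total;
# the counts are reproduced verbatim.
detector,file,tp,tn,fp,fn
custom,001,11780,1188216,2,2
custom,002,12413,1187556,16,15
custom,003,11274,1188723,1,2
custom,004,11209,1188758,18,15
custom,005,10524,1189468,4,4
custom,006,11580,1188405,8,7
custom,007,10794,1189197,2,7
custom,008,11085,1188871,25,19
custom,009,13366,1186524,56,54
custom,010,13411,1186489,45,55
physiozoo,001,11773,1188209,11,9
physiozoo,002,12417,1188484,3,11
physiozoo,003,11270,1187595,6,6
physiozoo,004,11222,1188730,3,2
physiozoo,005,10521,1189491,9,7
physiozoo,006,11574,1188412,7,13
physiozoo,007,10785,1189199,11,16
physiozoo,008,11072,1188864,29,32
physiozoo,009,13348,1186497,73,72
physiozoo,010,13410,1186419,53,56
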