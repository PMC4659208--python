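# Published total cerebral flow rates (ml/s) of the original 3D imaging
# study, per anatomical configuration and RICA stenosis degree.  Packaged
# as the input fixture for the percentage-change table reproduction; these
# are printed reference values, not outputs of this package's solver.
degree,COMPLETE,ACOA_ABSENT,RPCOA_ABSENT,LPCOA_ABSENT,RA1_ABSENT,LA1_ABSENT
0,12.51,12.45,12.34,12.34,11.72,11.79
25,12.04,12.10,12.03,11.99,11.55,11.46
50,10.91,10.95,10.93,10.85,10.64,10.27
75,8.79,8.75,8.80,8.74,8.79,8.05
90,8.20,8.14,8.19,8.10,8.18,7.41
100,8.16,8.07,8.14,8.08,8.16,7.37
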