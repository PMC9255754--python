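# Published annual SECR density estimates (individuals/ha) and capture counts from
# an 18-year salt-marsh harvest mouse grid-trapping program (Suisun Marsh, CA).
# One column pair per trapping design: the full 10x10/4-night grid and its
# subsampled variants (n x n sub-grids, checkerboard half-density, 3-night).
year,D_full,n_full,D_9x9,n_9x9,D_8x8,n_8x8,D_7x7,n_7x7,D_6x6,n_6x6,D_half,n_half,D_3day,n_3day
2000,26.11,34,29.43,31,34.04,28,33.81,23,37.28,18,20.79,19,28.08,33
2001,32.03,41,31.39,32,31.19,25,24.19,16,27.33,13,33.55,30,32.39,37
2002,44.9,58,40.49,42,38.98,32,35.47,24,39.48,19,40.73,37,48.87,56
2003,26.93,35,24.88,26,27.13,22,26.84,18,33.51,16,21.82,20,25.57,30
2004,28.66,37,25.43,26,27.85,22,23.18,15,18.95,9,22.85,21,31.42,36
2005,53.84,69,55.59,57,58.57,47,53.35,35,63.26,30,60.62,54,50.04,57
2006,16.88,22,15.06,16,14.31,12,11.6,8,10.57,5,18.42,17,17.04,20
2007,53.26,69,55.45,58,51.55,42,53.36,36,54.46,26,50.95,46,52.61,61
2008,33.4,43,31.91,33,29.59,24,30.83,21,31.31,15,34.41,31,34.9,40
2009,51.85,67,51.88,54,52.04,42,49.38,33,50.69,24,51.8,47,55.08,63
2010,42.89,55,41.91,43,41.54,33,39.43,26,41.89,20,43.43,39,41.89,48
2011,15.6,20,15.42,16,15.04,12,16.57,11,20.94,10,18.04,16,16.68,19
2012,20.54,27,17.86,19,18.13,15,17.57,12,16.54,8,21.66,20,20.9,25
2013,21.63,28,23.14,24,24.42,20,19.55,13,25.13,12,27.28,25,22.48,26
2014,28.39,37,27.5,29,25.53,21,23.21,16,25.13,12,30.35,28,28.09,33
2015,23.73,31,26.45,28,26.4,22,29.18,20,37.28,18,24.73,23,21.87,26
2016,23.82,31,25.06,26,21.95,18,20.88,14,18.74,9,26.41,24,20.54,24
2017,9.13,12,8.58,9,9.62,8,11.6,8,16.54,8,9.72,9,9.29,11
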