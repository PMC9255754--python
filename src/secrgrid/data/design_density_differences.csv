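# Published per-year density differences (individuals/ha), full design minus each
# subsampled design, from the same 18-year monitoring program as
# annual_density_estimates.csv. Signs follow the full-minus-reduced convention.
# Column assignment for the half-density and 3-night designs was validated against
# the density table (difference = D_full - D_design to printed rounding).
year,D_full,d_9x9,d_8x8,d_7x7,d_6x6,d_half,d_3day
2000,26.11,-3.32,-7.94,-7.71,-11.17,5.31,-1.98
2001,32.03,0.63,0.84,7.84,4.70,-1.52,-0.36
2002,44.91,4.41,5.93,9.44,5.42,4.17,-3.97
2003,26.93,2.04,-0.20,0.08,-6.58,5.11,1.36
2004,28.66,3.23,0.80,5.47,9.70,5.81,-2.76
2005,53.84,-1.75,-4.73,0.49,-9.42,-6.78,3.79
2006,16.89,1.82,2.57,5.28,6.31,-1.53,-0.16
2007,53.26,-2.20,1.71,-0.11,-1.20,2.31,0.65
2008,33.40,1.49,3.80,2.57,2.09,-1.01,-1.50
2009,51.85,-0.04,-0.19,2.46,1.15,0.04,-3.23
2010,42.90,0.98,1.35,3.46,1.00,-0.54,1.00
2011,15.61,0.18,0.57,-0.96,-5.34,-2.44,-1.08
2012,20.55,2.68,2.41,2.98,4.00,-1.11,-0.36
2013,21.64,-1.51,-2.79,2.08,-3.50,-5.65,-0.85
2014,28.40,0.89,2.86,5.18,3.26,-1.96,0.31
2015,23.74,-2.71,-2.67,-5.44,-13.55,-1.00,1.86
2016,23.83,-1.24,1.87,2.94,5.08,-2.59,3.29
2017,9.13,0.55,-0.49,-2.47,-7.41,-0.59,-0.16
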