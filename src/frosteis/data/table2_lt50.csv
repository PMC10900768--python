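# Reference LT50 table: semi-lethal temperatures (mean +/- SE, deg C) of
# sapwood tissue from Korean pine (Pi) and Simon poplar (Po), 2 cooling
# rates (Slow = 2 C/min, Fast = 10 C/min) x 6 moisture-content levels x
# 2 freezing durations. The air-dry moisture level is labelled 10% here,
# following the published table, although the conditioning text gives 15%.
species,cooling_rate_label,mc_pct,duration_h,lt50_mean_c,lt50_se_c
Pi,Slow,200,0.5,-60.50,1.55
Pi,Slow,150,0.5,-57.31,1.29
Pi,Slow,100,0.5,-52.83,2.37
Pi,Slow,80,0.5,-51.62,1.67
Pi,Slow,30,0.5,-49.44,1.52
Pi,Slow,10,0.5,-50.30,1.71
Pi,Slow,200,1,-43.86,2.91
Pi,Slow,150,1,-41.29,2.27
Pi,Slow,100,1,-40.68,2.03
Pi,Slow,80,1,-32.13,2.34
Pi,Slow,30,1,-25.13,1.75
Pi,Slow,10,1,-23.88,1.90
Pi,Fast,200,0.5,-41.02,1.49
Pi,Fast,150,0.5,-42.61,1.24
Pi,Fast,100,0.5,-43.02,1.76
Pi,Fast,80,0.5,-39.09,1.55
Pi,Fast,30,0.5,-40.02,1.99
Pi,Fast,10,0.5,-38.10,1.28
Pi,Fast,200,1,-30.35,1.56
Pi,Fast,150,1,-31.20,1.44
Pi,Fast,100,1,-31.82,1.48
Pi,Fast,80,1,-29.78,1.90
Pi,Fast,30,1,-21.05,1.93
Pi,Fast,10,1,-20.00,1.97
Po,Slow,200,0.5,-57.23,1.36
Po,Slow,150,0.5,-58.25,1.59
Po,Slow,100,0.5,-56.78,3.10
Po,Slow,80,0.5,-41.58,1.50
Po,Slow,30,0.5,-50.98,1.40
Po,Slow,10,0.5,-40.81,1.78
Po,Slow,200,1,-54.86,1.34
Po,Slow,150,1,-54.34,2.76
Po,Slow,100,1,-51.27,1.53
Po,Slow,80,1,-36.49,2.39
Po,Slow,30,1,-44.16,1.41
Po,Slow,10,1,-33.77,1.66
Po,Fast,200,0.5,-47.61,1.59
Po,Fast,150,0.5,-49.93,1.99
Po,Fast,100,0.5,-48.02,1.74
Po,Fast,80,0.5,-47.80,1.32
Po,Fast,30,0.5,-44.00,1.94
Po,Fast,10,0.5,-44.36,1.58
Po,Fast,200,1,-41.98,1.49
Po,Fast,150,1,-42.41,1.95
Po,Fast,100,1,-43.16,0.91
Po,Fast,80,1,-39.81,1.51
Po,Fast,30,1,-32.14,1.59
Po,Fast,10,1,-30.60,1.52
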