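source,dose,time_h,metric,mean,dispersion
synthetic,0 uM,0.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,12.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,24.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,36.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,48.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,60.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,72.0,gammaH2AX_pct,2.3,0.73
synthetic,0 uM,0.0,cell_count,1000.0,80.0
synthetic,0 uM,12.0,cell_count,1383.1,103.0
synthetic,0 uM,24.0,cell_count,1912.9,134.8
synthetic,0 uM,36.0,cell_count,2645.8,178.7
synthetic,0 uM,48.0,cell_count,3659.3,239.6
synthetic,0 uM,60.0,cell_count,5061.1,323.7
synthetic,0 uM,72.0,cell_count,7000.0,440.0
synthetic,0.3 uM,0.0,gammaH2AX_pct,2.3,0.73
synthetic,0.3 uM,12.0,gammaH2AX_pct,4.59,0.96
synthetic,0.3 uM,24.0,gammaH2AX_pct,5.76,1.08
synthetic,0.3 uM,36.0,gammaH2AX_pct,6.36,1.14
synthetic,0.3 uM,48.0,gammaH2AX_pct,6.67,1.17
synthetic,0.3 uM,60.0,gammaH2AX_pct,6.83,1.18
synthetic,0.3 uM,72.0,gammaH2AX_pct,6.91,1.19
synthetic,0.3 uM,0.0,cell_count,1000.0,80.0
synthetic,0.3 uM,12.0,cell_count,1355.4,101.3
synthetic,0.3 uM,24.0,cell_count,1837.1,130.2
synthetic,0.3 uM,36.0,cell_count,2490.0,169.4
synthetic,0.3 uM,48.0,cell_count,3374.9,222.5
synthetic,0.3 uM,60.0,cell_count,4574.3,294.5
synthetic,0.3 uM,72.0,cell_count,6200.0,392.0
synthetic,1 uM,0.0,gammaH2AX_pct,2.3,0.73
synthetic,1 uM,12.0,gammaH2AX_pct,16.75,2.18
synthetic,1 uM,24.0,gammaH2AX_pct,24.17,2.92
synthetic,1 uM,36.0,gammaH2AX_pct,27.98,3.3
synthetic,1 uM,48.0,gammaH2AX_pct,29.94,3.49
synthetic,1 uM,60.0,gammaH2AX_pct,30.94,3.59
synthetic,1 uM,72.0,gammaH2AX_pct,31.46,3.65
synthetic,1 uM,0.0,cell_count,1000.0,80.0
synthetic,1 uM,12.0,cell_count,1213.9,92.8
synthetic,1 uM,24.0,cell_count,1473.6,108.4
synthetic,1 uM,36.0,cell_count,1788.9,127.3
synthetic,1 uM,48.0,cell_count,2171.5,150.3
synthetic,1 uM,60.0,cell_count,2636.1,178.2
synthetic,1 uM,72.0,cell_count,3200.0,212.0
synthetic,3 uM,0.0,gammaH2AX_pct,2.3,0.73
synthetic,3 uM,12.0,gammaH2AX_pct,30.38,3.54
synthetic,3 uM,24.0,gammaH2AX_pct,44.79,4.98
synthetic,3 uM,36.0,gammaH2AX_pct,52.19,5.72
synthetic,3 uM,48.0,gammaH2AX_pct,55.99,6.1
synthetic,3 uM,60.0,gammaH2AX_pct,57.94,6.29
synthetic,3 uM,72.0,gammaH2AX_pct,58.94,6.39
synthetic,3 uM,0.0,cell_count,1000.0,80.0
synthetic,3 uM,12.0,cell_count,1112.9,86.8
synthetic,3 uM,24.0,cell_count,1238.6,94.3
synthetic,3 uM,36.0,cell_count,1378.4,102.7
synthetic,3 uM,48.0,cell_count,1534.0,112.0
synthetic,3 uM,60.0,cell_count,1707.2,122.4
synthetic,3 uM,72.0,cell_count,1900.0,134.0
synthetic,10 uM,0.0,gammaH2AX_pct,2.3,0.73
synthetic,10 uM,12.0,gammaH2AX_pct,34.76,3.98
synthetic,10 uM,24.0,gammaH2AX_pct,51.42,5.64
synthetic,10 uM,36.0,gammaH2AX_pct,59.97,6.5
synthetic,10 uM,48.0,gammaH2AX_pct,64.37,6.94
synthetic,10 uM,60.0,gammaH2AX_pct,66.62,7.16
synthetic,10 uM,72.0,gammaH2AX_pct,67.78,7.28
synthetic,10 uM,0.0,cell_count,1000.0,80.0
synthetic,10 uM,12.0,cell_count,1069.9,84.2
synthetic,10 uM,24.0,cell_count,1144.7,88.7
synthetic,10 uM,36.0,cell_count,1224.7,93.5
synthetic,10 uM,48.0,cell_count,1310.4,98.6
synthetic,10 uM,60.0,cell_count,1402.0,104.1
synthetic,10 uM,72.0,cell_count,1500.0,110.0
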