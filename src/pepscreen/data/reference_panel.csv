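week,peptide_id,mass_da,mt_min,protein,mean_N,freq_N,mean_HA,freq_HA,mean_HL,freq_HL,fold_HA,fold_HL
1,7035,1197.6,37.2,Actin alpha skeletal muscle,482.2,91.7,195.8,16.7,0.0,0.0,-2.46,na
1,10615,1433.7,39.2,Collagen alpha-1(I) chain precursor,506.7,100.0,164.9,50.0,483.4,40.0,-3.07,-1.05
1,13476,1652.8,40.9,Collagen alpha-2(I) chain,452.8,91.7,0.0,0.0,67.6,20.0,na,-6.70
1,13640,1668.9,35.1,Hemoglobin subunit beta-1,0.0,0.0,5343.6,100.0,3360.0,100.0,na,na
1,17766,2088.1,36.3,Collagen alpha-1(I) chain precursor,102.5,100.0,0.0,0.0,93.6,20.0,na,-1.09
1,7744,1240.6,31.4,alpha-1-inhibitor 3 precursor,0.0,0.0,4339.0,100.0,2920.1,100.0,na,na
1,14576,1759.9,34.0,L-lactate dehydrogenase B chain,615.4,91.7,67.1,66.7,66.0,60.0,-9.17,-9.32
1,13862,1691.9,35.2,Collagen alpha-1(I) chain,336.8,100.0,89.1,16.7,250.8,60.0,-3.78,-1.34
1,11124,1470.8,32.6,Hemoglobin subunit alpha-1/2,39.0,8.3,1755.1,100.0,1770.7,100.0,45.04,45.44
1,10647,1435.7,31.1,Seminal vesicle secretory protein 2 precursor,838.1,75.0,2676.8,100.0,2623.0,80.0,3.19,3.13
1,13451,1649.8,41.3,Apolipoprotein A-IV,1863.1,100.0,847.2,100.0,1080.5,100.0,-2.20,-1.72
1,11115,1469.7,39.3,Collagen alpha-1(III) chain,271.6,91.7,25.4,16.7,0.0,0.0,-10.70,na
2,10013,1388.7,39.2,Collagen alpha-1(I) chain,3710.4,100.0,892.4,80.0,1133.4,100.0,-4.16,-3.27
2,13862,1691.9,35.2,Collagen alpha-1(I) chain,466.0,100.0,0.0,0.0,306.4,16.7,na,-1.52
2,14941,1795.9,41.6,Collagen alpha-2(I) chain,146.7,100.0,0.0,0.0,14.9,16.7,na,-9.88
2,8057,1260.7,38.4,Collagen alpha-1(I) chain,675.8,100.0,0.0,0.0,271.4,16.7,na,-2.49
2,24835,3124.6,32.9,Seminal vesicle protein 2 precursor,0.0,0.0,1421.0,100.0,947.8,100.0,na,na
2,17689,2081.0,26.9,Collagen alpha-2(I) chain,1593.7,100.0,615.3,80.0,829.7,100.0,-2.59,-1.92
2,11667,1511.7,39.3,Procollagen type IX alpha 3 isoform CRA a,125.4,91.7,0.0,0.0,0.0,0.0,na,na
2,9863,1378.7,39.2,Collagen alpha-1(II) chain,825.0,100.0,705.3,20.0,281.0,83.3,-1.17,-2.94
2,10377,1414.7,38.7,Contrapsin-like protease inhibitor 3 precursor,324.1,100.0,75.4,40.0,0.0,0.0,-4.30,na
2,13429,1647.8,40.5,Collagen alpha-1(I) chain,101.1,16.7,0.0,0.0,762.1,66.7,na,7.54
2,13543,1659.8,39.7,alpha 4 type V collagen,156.0,100.0,307.6,20.0,260.1,100.0,1.97,1.67
2,15097,1811.9,42.1,Collagen alpha-1(III) chain,188.6,66.7,535.0,100.0,0.0,0.0,2.84,na
2,7243,1210.6,38.0,Fibrinogen alpha chain precursor,99.2,66.7,499.0,80.0,101.7,16.7,5.03,1.03
2,8984,1320.7,38.2,Collagen alpha-1(III) chain,861.3,100.0,798.5,80.0,1560.3,100.0,-1.08,1.81
2,2712,933.5,47.2,Collagen alpha-1(II) chain,13.3,33.3,0.0,0.0,27.4,66.7,na,2.06
2,4970,1066.5,36.7,Collagen alpha-1(II) chain,408.7,75.0,984.6,100.0,377.9,33.3,2.41,-1.08
2,9955,1384.7,32.7,Extracellular superoxide dismutase (Cu-Zn) precursor,415.5,66.7,2275.0,100.0,266.7,33.3,5.47,-1.56
2,10240,1405.7,39.1,Collagen alpha-1(I) chain,1005.1,91.7,1430.2,60.0,1830.2,100.0,1.42,1.82
2,11153,1472.7,49.2,Collagen alpha-1(I) chain,0.0,0.0,1478.7,80.0,170.1,33.3,na,na
2,10124,1396.7,31.8,Apolipoprotein A-IV,132.4,66.7,378.2,80.0,254.3,16.7,2.86,1.92
2,17855,2096.1,35.8,Apolipoprotein A-IV precursor,0.0,0.0,1731.4,100.0,642.7,100.0,na,na
2,9540,1354.6,48.8,Collagen alpha-2(I) chain,1212.4,100.0,382.3,40.0,697.7,50.0,-3.17,-1.74
2,12640,1584.8,34.0,Collagen alpha-1(I) chain,323.8,100.0,101.6,100.0,120.8,66.7,-3.19,-2.68
2,13476,1652.8,40.9,Collagen alpha-2(I) chain,541.2,91.7,304.1,20.0,0.0,0.0,-1.78,na
2,14976,1799.9,41.5,Proline-rich protein,441.3,83.3,51010.5,100.0,14119.9,100.0,115.59,32.00
2,4768,1051.5,36.5,Collagen alpha-1(I) chain,134.6,100.0,106.8,60.0,220.0,100.0,-1.26,1.63
2,20632,2428.3,26.6,Contrapsin-like protease inhibitor 1 precursor,84.2,16.7,254.8,80.0,983.1,100.0,3.03,11.68
2,15844,1887.9,40.9,Contrapsin-like protease inhibitor 6 precursor,62.1,33.3,450.6,80.0,135.7,16.7,7.25,2.18
2,4524,1035.5,35.6,Collagen alpha-1(III) chain,461.9,58.3,471.4,60.0,896.5,100.0,1.02,1.94
3,13476,1652.8,40.9,Collagen alpha-2(I) chain,624.1,100.0,171.8,33.3,192.1,50.0,-3.63,-3.25
3,14544,1756.9,41.9,Uromodulin,0.0,0.0,2190.6,100.0,976.5,100.0,na,na
3,10648,1435.7,39.6,Collagen alpha-1(I) chain precursor,1141.3,100.0,147.2,16.7,0.0,0.0,-7.75,na
3,8116,1263.6,32.3,Transketolase,392.6,100.0,66.1,50.0,104.0,100.0,-5.94,-3.77
3,13451,1649.8,41.3,Apolipoprotein A-IV,1740.8,100.0,509.9,100.0,922.7,100.0,-3.41,-1.89
3,17002,2008.0,31.2,Collagen alpha-1(III) chain,507.3,100.0,68.9,33.3,136.2,100.0,-7.36,-3.72
3,14576,1759.9,34.0,L-lactate dehydrogenase B chain,683.8,100.0,31.0,16.7,150.3,83.3,-22.03,-4.55
3,16532,1960.0,35.5,Collagen alpha-1(I) chain,170.7,100.0,0.0,0.0,97.1,50.0,na,-1.76
3,17766,2088.1,36.3,Collagen alpha-1(I) chain precursor,164.6,100.0,20.0,16.7,79.9,50.0,-8.22,-2.06
3,13970,1702.0,22.8,alpha-1-acid glycoprotein precursor,0.0,0.0,75.3,50.0,303.6,100.0,na,na
3,19332,2260.0,26.3,Fibrinogen alpha chain precursor,28.4,9.1,10.6,16.7,47.4,83.3,-2.69,1.67
3,4486,1032.5,36.9,Collagen alpha-1(XVII) chain,12.4,36.4,8.1,16.7,21.3,83.3,-1.52,1.72
3,8197,1269.6,39.2,Collagen alpha-2(I) chain,30.4,45.5,130.6,83.3,13.9,50.0,4.30,-2.19
3,5870,1124.6,30.8,Cd99 protein,10.5,9.1,0.0,0.0,21.0,50.0,na,1.99
3,21145,2497.4,38.7,Serine (or cysteine) peptidase inhibitor clade F member 2,34.6,9.1,71.2,33.3,161.9,83.3,2.06,4.69
3,18962,2216.1,26.6,Similar to CG7896-PA,0.0,0.0,22.4,33.3,36.1,83.3,na,na
3,17050,2013.0,36.7,Osteopontin precursor,26.9,54.5,58.8,33.3,57.7,100.0,2.19,2.15
3,5198,1079.5,47.6,Collagen alpha-1(III) chain,9.2,63.6,0.0,0.0,15.0,66.7,na,1.62
4,6975,1194.6,37.7,Collagen alpha-1(I) chain,12172.0,100.0,6619.6,100.0,6543.0,100.0,-1.84,-1.86
4,11644,1509.8,27.3,Collagen alpha-1(I) chain precursor,52.9,83.3,50.7,16.7,187.6,100.0,-1.04,3.55
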