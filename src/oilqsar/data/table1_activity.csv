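id,name,chemclass,lc50_iii,lc50_iii_lo,lc50_iii_hi,lc50_iv,lc50_iv_lo,lc50_iv_hi,lc50_pupae,lc50_pupae_lo,lc50_pupae_hi,pupae_censored
1,p-Anisaldehyde,Benzaldehyde,18.0,15.5,20.4,18.8,16.9,20.6,96.4,92.5,100.2,0
2,Camphor,Bicyclic monoterpenoid,22.3,21.6,23.9,25.8,23.6,27.9,245.1,234.6,255.5,0
3,3-Carene,Bicyclic monoterpene,24.7,23.7,25.7,25.5,24.3,26.7,105.5,101.8,109.1,0
4,Carvacrol,Cyclic monoterpenoid,5.5,5.28,5.72,7.7,7.3,8.1,53.2,51.8,54.5,0
5,Carveol,Cyclic monoterpenoid,103.0,99.4,109.9,104.6,102.0,107.2,249.0,241.8,256.1,0
6,Carvomenthol,Cyclic monoterpenoid,198.2,183.69,212.71,219.8,206.6,232.9,452.2,435.2,469.1,0
7,(+)-Carvone,Cyclic monoterpenoid,150.2,149.0,151.4,150.2,145.5,154.8,500.6,495.0,506.1,0
8,Carvotanacetol,Cyclic monoterpenoid,152.3,148.2,156.8,198.3,192.1,204.44,245.1,238.1,252.0,0
9,beta-Caryophyllene,Bicyclic sesquiterpene,45.6,43.8,47.2,47.7,42.2,52.9,222.3,216.8,27.7,0
10,Citronellal,Acyclic monoterpenoid,105.3,98.3,102.3,124.9,123.2,125.6,549.2,557.35,565.5,0
11,beta-Citronellol,Acyclic monoterpenoid,90.4,88.9,91.9,94.8,93.4,95.2,203.1,198.44,207.76,0
12,m-Cresol,Phenolic derivative,60.0,58.8,61.2,60.6,59.3,61.9,107.7,104.94,110.4,0
13,o-Cresol,Phenolic derivative,54.8,53.6,56.0,54.4,53.8,54.0,105.6,103.4,107.7,0
14,Cuminaldehyde,Benzaldehyde,23.0,22.0,24.0,23.9,22.0,25.8,95.4,91.1,99.6,0
15,p-Cymene,Cyclic monoterpene,23.1,22.3,24.9,24.0,23.8,26.2,306.3,298.4,314.1,0
16,trans-Dihydrocarvone,Cyclic monoterpene,345.0,340.8,350.1,361.3,346.2,366.4,708.6,698.1,719.1,0
17,"3,4-Dimethylcumene",Phenolic derivative,35.6,33.5,37.7,47.7,46.2,49.2,105.5,101.9,109.1,0
18,Eucalyptol,Bicyclic monoterpenoid,48.0,47.9,49.1,44.4,43.3,45.5,92.9,86.2,99.6,0
19,Geranial,Acyclic monoterpenoid,52.2,51.1,53.3,53.4,49.9,56.8,193.9,186.8,200.9,0
20,Geraniol,Acyclic monoterpenoid,20.4,19.78,21.02,20.4,19.4,21.3,104.6,101.9,107.2,0
21,Germacrene-D,Sesquiterpene,45.4,44.3,46.6,45.6,46.71,47.49,229.0,222.7,235.2,0
22,alpha-Humulene,Bicyclic sesquiterpene,100.5,98.2,102.7,101.8,100.0,103.5,508.3,497.17,519.43,0
23,Hydrocarvone,Cyclic monoterpene,1351.6,1228.68,1474.5,1470.9,1347.9,1592.9,2000,,,1
24,Hydrodihydrocarvone,Cyclic monoterpene,1416.5,1152.4,1680.1,1628.2,1364.6,1889.3,2000,,,1
25,3-Isopropylphenol,Cyclic monoterpene,21.3,20.9,21.6,23.1,21.2,24.9,100.2,96.4,104.4,0
26,Isoborneol,Bicyclic monoterpenoid,91.9,89.7,94.0,97.1,94.1,100.1,206.1,199.7,213.5,0
27,Isopulegol,Cyclic monoterpene,247.4,234.4,250.9,297.3,290.2,304.3,610.8,604.6,616.9,0
28,trans-Isopulegone,Cyclic monoterpene,529.1,510.1,537.1,538.8,530.7,546.8,908.6,896.2,920.9,0
29,Lavandulol,Acyclic monoterpenoid,52.2,51.0,53.3,56.5,53.3,59.9,238.7,224.6,252.7,0
30,Limonene,Cyclic monoterpene,24.2,23.4,24.9,27.3,23.3,28.2,98.4,95.4,101.4,0
31,Linalool,Acyclic monoterpenoid,26.8,26.0,27.5,30.7,29.7,31.6,249.0,241.8,256.1,0
32,Menthol,Cyclic monoterpenoid,443.6,432.3,443.2,404.1,381.1,427.0,529.1,521.0,537.1,0
33,Menthone,Cyclic monoterpenoid,500.6,495.0,506.1,508.9,500.8,516.9,878.5,867.4,889.5,0
34,Myrcene,Acyclic monoterpene,19.5,18.5,20.4,19.1,18.0,20.2,31.8,30.2,33.2,0
35,Neoisopulegol,Cyclic monoterpenoid,458.4,450.2,466.6,554.2,545.6,562.7,908.6,896.2,920.9,0
36,(-)-Perillaldehyde,Cyclic monoterpenoid,95.9,94.8,97.0,115.8,113.0,118.6,429.1,422.9,435.22,0
37,beta-Phellandrene,Cyclic monoterpene,490.7,483.1,498.2,554.3,545.8,563.0,908.6,896.3,920.9,0
38,alpha-Pinene,Bicyclic monoterpene,24.4,23.2,25.5,25.5,22.0,28.97,98.4,95.4,101.4,0
39,beta-Pinene,Bicyclic monoterpene,19.6,18.82,20.38,24.3,22.8,25.7,96.9,89.9,103.9,0
40,(+)-Pulegone,Cyclic monoterpenoid,168.7,665.8,171.59,188.1,185.29,190.91,496.2,490.4,501.9,0
41,Rotundifolone,Cyclic monoterpenoid,58.9,57.8,59.9,62.5,61.5,63.5,287.4,279.4,295.3,0
42,Sabinene,Bicyclic monoterpene,53.7,51.9,55.4,59.0,58.3,60.7,268.0,262.5,273.0,0
43,alpha-Terpinene,Cyclic monoterpene,13.8,12.9,14.7,13.6,12.8,14.3,209.5,204.0,214.9,0
44,gamma-Terpinene,Cyclic monoterpene,45.4,44.3,46.5,56.8,55.7,57.9,287.4,280.2,294.6,0
45,4-Terpineol,Cyclic monoterpenoid,94.2,91.1,97.3,97.7,90.6,104.8,201.8,195.6,208.0,0
46,alpha-Terpineol,Cyclic monoterpenoid,95.9,93.8,98.0,98.4,95.3,101.4,206.1,198.4,213.7,0
47,beta-Terpineol,Cyclic monoterpenoid,101.3,99.5,103.0,107.4,103.9,110.8,508.3,497.1,519.43,0
48,gamma-Terpineol,Cyclic monoterpenoid,100.5,98.3,102.7,103.6,100.0,109.9,4965.5,4949.1,4981.9,0
49,Terpinolene,Cyclic monoterpene,20.4,19.6,21.2,18.6,16.9,20.2,107.4,103.9,110.8,0
50,Thymol,Cyclic monoterpenoid,11.1,10.28,11.9,12.2,11.7,12.7,111.4,108.5,114.2,0
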