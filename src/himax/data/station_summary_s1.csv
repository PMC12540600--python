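station_code,city,state,source,latitude_deg_n,longitude_deg_w,elevation_m,missing_days,missing_pct,hismax24_threshold_f,underestimation_pct,out_of_range_pct
ALBNY,Albany,NY,ISD-lite,42.7,73.8,85.4,295,2.70,95.1,23.90,0
AVPPA,Pittston,PA,ISD-lite,41.3,75.7,289.9,236,2.20,94.1,21.00,0
BDRCT,Stratford,CT,ISD-lite,41.2,73.1,1.8,2212,20.20,95.0,25.40,0
BKWWV,Beaver,WV,ISD-lite,37.8,81.1,760.2,603,5.50,88.3,14.00,0
BOSMA,Boston,MA,ISD-lite,42.4,71.0,3.3,109,1.00,95.9,15.70,0
BTVVT,Burlington,VT,ISD-lite,44.5,73.2,101.1,117,1.10,92.8,20.60,0
BUFNY,Buffalo,NY,ISD-lite,42.9,78.7,216.2,2235,20.40,90.7,20.80,0
CARME,Caribou,ME,ISD-lite,46.9,68.0,188.6,2206,20.10,86.8,19.10,0
CONNH,Concord,NH,ISD-lite,43.2,71.5,103.2,247,2.30,94.1,17.10,0
EKNWV,Elkins,WV,ISD-lite,38.9,79.9,595.7,2287,20.90,90.4,20.50,0
PHLPA,Philadelphia,PA,ISD-lite,39.9,75.2,2.2,82,0.70,101.2,26.00,0.13
PITPA,Pittsburgh,PA,ISD-lite,40.5,80.2,341.0,34,0.30,93.9,16.10,0
RICVA,Richmond,VA,ISD-lite,37.5,77.3,50.7,65,0.60,103.9,26.40,0.02
ASTTX,Austin,TX,USCRN,30.6,98.1,136.1,886,15.20,102.1,20.00,0
BDFIN,Bedford,IN,USCRN,38.9,86.6,76.0,304,5.20,100.9,21.10,0.21
BDGCA,Bodega,CA,USCRN,38.3,123.1,6.3,1187,20.30,67.2,7.40,0
BOLCO,Boulder,CO,USCRN,40.0,105.5,1982.8,711,12.20,71.8,5.70,0
BRCUT,Brigham City,UT,USCRN,41.6,112.5,495.1,1011,17.30,90.5,24.20,0
BWKGA,Brunswick,GA,USCRN,30.8,81.5,2.5,443,7.60,104.9,53.60,0.18
CBYOR,Coos Bay,OR,USCRN,43.3,124.3,1.2,529,9.10,71.1,5.60,0
DARWA,Darrington,WA,USCRN,48.5,121.4,40.7,1026,17.60,89.5,6.50,0
DILMT,Dillon,MT,USCRN,45.2,113.0,597.1,741,12.70,84.5,1.50,0
DMNIA,Des Moines,IA,USCRN,41.6,93.3,92.1,307,5.30,103.0,19.20,0.35
DURNC,Durham,NC,USCRN,36.0,79.1,56.2,725,12.40,100.0,29.90,0
FHPAL,Fairhope,AL,USCRN,30.5,87.9,9.5,272,4.70,106.7,62.70,0.51
GLDMI,Gaylord,MI,USCRN,44.9,84.7,146.1,721,12.30,86.7,13.30,0
HSPMS,Holly Springs,MS,USCRN,34.8,89.4,48.4,269,4.60,104.6,38.90,0.13
JMTND,Jamestown,ND,USCRN,46.8,99.5,192.0,721,12.30,91.8,16.70,0.05
JOPMO,Joplin,MO,USCRN,37.4,94.6,95.2,304,5.20,104.8,38.00,0.04
LCRNM,Las Cruces,NM,USCRN,32.6,106.7,432.7,530,9.10,95.9,14.50,0
OAKKS,Oakley,KS,USCRN,38.9,101.0,287.0,377,6.50,99.9,30.60,0.05
PTATX,Port Aransas,TX,USCRN,28.3,96.8,1.5,677,11.60,111.2,46.80,4.68
SEBFL,Sebring,FL,USCRN,27.2,81.4,15.0,1039,17.80,103.9,42.90,0.05
SNDWY,Sundance,WY,USCRN,44.5,104.4,579.2,756,12.90,82.8,8.80,0
STBCA,Santa Barbara,CA,USCRN,34.4,119.9,1.8,889,15.20,77.0,3.40,0
WMSAZ,Williams,AZ,USCRN,35.8,112.3,599.0,561,9.60,89.0,5.70,0
YMAAZ,Yuma,AZ,USCRN,32.8,114.2,62.0,480,8.20,109.1,43.50,0.04
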