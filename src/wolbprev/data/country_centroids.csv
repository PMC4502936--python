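country,latitude,longitude,continent
American Samoa,-14.3,-170.7,Oceania
Australia,-25.3,133.8,Australia
Austria,47.6,14.1,Europe
Belarus,53.7,28.0,Europe
Belgium,50.5,4.5,Europe
Brazil,-14.2,-51.9,South America
Canada,56.1,-106.3,North America
Chile,-35.7,-71.5,South America
China,35.9,104.2,Asia
Colombia,4.6,-74.3,South America
Croatia,45.1,15.2,Europe
Czech Republic,49.8,15.5,Europe
Denmark,56.3,9.5,Europe
Ecuador,-1.8,-78.2,South America
Egypt,26.8,30.8,Africa
Fiji,-17.7,178.0,Oceania
Finland,61.9,25.7,Europe
France,46.2,2.2,Europe
Germany,51.2,10.5,Europe
Greece,39.1,21.8,Europe
Hungary,47.2,19.5,Europe
India,20.6,79.0,Asia
Indonesia,-0.8,113.9,Asia
Iran,32.4,53.7,Asia
Italy,41.9,12.6,Europe
Japan,36.2,138.3,Asia
Kazakhstan,48.0,66.9,Asia
Kenya,0.0,37.9,Africa
Madagascar,-18.8,46.9,Africa
Malaysia,4.2,102.0,Asia
Mexico,23.6,-102.6,North America
Mongolia,46.9,103.8,Asia
Netherlands,52.1,5.3,Europe
New Zealand,-40.9,174.9,Oceania
Norway,60.5,8.5,Europe
Pakistan,30.4,69.3,Asia
Panama,8.5,-80.8,North America
Papua New Guinea,-6.3,143.9,Oceania
Peru,-9.2,-75.0,South America
Philippines,12.9,121.8,Asia
Poland,51.9,19.1,Europe
Portugal,39.4,-8.2,Europe
Romania,45.9,25.0,Europe
Russia,61.5,105.3,Europe
Slovakia,48.7,19.7,Europe
Slovenia,46.2,15.0,Europe
South Africa,-30.6,22.9,Africa
South Korea,35.9,127.8,Asia
Spain,40.5,-3.7,Europe
Sri Lanka,7.9,80.8,Asia
Sweden,60.1,18.6,Europe
Switzerland,46.8,8.2,Europe
Taiwan,23.7,121.0,Asia
Tanzania,-6.4,34.9,Africa
Thailand,15.9,101.0,Asia
Turkey,39.0,35.2,Asia
Uganda,1.4,32.3,Africa
UK,55.4,-3.4,Europe
Ukraine,48.4,31.2,Europe
USA,37.1,-95.7,North America
Vietnam,14.1,108.3,Asia
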