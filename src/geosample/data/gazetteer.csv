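alias,country_code
USA,USA
US,USA
United States,USA
U.S.A.,USA
UK,GBR
Great Britain,GBR
England,GBR
Scotland,GBR
Wales,GBR
Northern Ireland,GBR
South Korea,KOR
Korea South,KOR
North Korea,PRK
Russia,RUS
Vietnam,VNM
Czech Republic,CZE
The Netherlands,NLD
Holland,NLD
Tanzania,TZA
Bolivia,BOL
Venezuela,VEN
Iran,IRN
Syria,SYR
Laos,LAO
DR Congo,COD
DRC,COD
Democratic Republic of Congo,COD
Congo DR,COD
Republic of the Congo,COG
Congo-Brazzaville,COG
Ivory Coast,CIV
Cape Verde,CPV
Swaziland,SWZ
Burma,MMR
Brunei,BRN
Moldova,MDA
Macedonia,MKD
Palestine,PSE
The Gambia,GMB
The Bahamas,BHS
Micronesia,FSM
Turkiye,TUR
East Timor,TLS
Macau,MAC
United Arab Emirates (UAE),ARE
UAE,ARE
Slovak Republic,SVK
Kyrgyz Republic,KGZ
Sao Tome,STP
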