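name,state,date
New St. John Fellowship Baptist Church shooting,LA,1999-03-10
Columbine High School massacre,CO,1999-04-20
Albertson's supermarket shooting,NV,1999-06-03
Day-trading firms shooting,GA,1999-07-29
Wedgwood Baptist Church shooting,TX,1999-09-15
Xerox Engineering Systems shootings,HI,1999-11-02
Raddison Bay Harbor shooting,FL,1999-12-30
Mi-T-Fine Car Wash shooting,TX,2000-03-20
Mount Lebanon shooting,PA,2000-04-28
Edgewater Technology shooting,MA,2000-12-26
Navistar International shooting,IL,2001-02-05
Bookcliff RV Park shooting,CO,2001-07-03
Burns International Security shooting,CA,2001-09-08
Bertrand Products shooting,IN,2002-03-22
Labor Ready shooting,AL,2003-02-25
Lockheed Martin shooting,MS,2003-07-08
Windy City Core Supply shooting,IL,2003-08-27
Stateline Tavern shooting,ID,2003-10-24
ConAgra Foods Plant shooting,KS,2004-07-03
Sawyer County woods shooting,WI,2004-11-21
Damageplan show shooting,OH,2004-12-08
Fulton County Courthouse shooting,GA,2005-03-11
Living Church of God shooting,WI,2005-03-12
Red Lake Indian reservation shooting,MN,2005-03-21
Sash Assembly of God shooting,TX,2005-08-29
Postal facility shooting,CA,2006-01-30
Capitol Hill shooting,WA,2006-03-25
The Ministry of Jesus Christ shooting,LA,2006-05-21
West Nickel Mines Amish School shooting,PA,2006-10-02
Trolley Square shooting,UT,2007-02-12
Virginia Tech shooting,VA,2007-04-16
Crandon duplex shooting,WI,2007-10-07
Westroads Mall shooting,NE,2007-12-05
Youth With a Mission and New Life Church shooting,CO,2007-12-09
City council shooting,MO,2008-02-07
Northern Illinois University shooting,IL,2008-02-14
Black Road Auto shooting,CA,2008-03-18
Atlantis Plastics shooting,KY,2008-06-25
Skagit County shooting,WA,2008-09-02
Pinelake Health and Rehab Center shooting,NC,2009-03-29
Immigration services center shooting,NY,2009-04-03
Worth Street shooting,NC,2009-11-01
Army processing center shooting,TX,2009-11-05
Pierce County coffee shop shooting,WA,2009-11-29
Hot Spot Cafe shooting,CA,2010-04-03
Yoyito Cafe-Restaurant shooting,FL,2010-06-06
Hartford Beer Distributors shooting,CT,2010-08-03
City Grill shooting,NY,2010-08-14
Safeway parking lot shooting,AZ,2011-01-08
Family Law Practice shooting,AZ,2011-06-02
Forum Roller World shooting,TX,2011-07-23
IHOP shooting,NV,2011-09-06
Salon Meritage shooting,CA,2011-10-12
Su Jung Health Sauna shooting,GA,2012-02-21
Oikos University shooting,CA,2012-04-02
Cafe Racer shooting,WA,2012-05-30
Century 16 movie theater shooting,CO,2012-07-20
Sikh temple of Wisconsin shooting,WI,2012-08-05
Accent Signage Systems shooting,MN,2012-09-27
Sandy Hook Elementary School shooting,CT,2012-12-14
Mohawk Valley shootings,NY,2013-03-13
Pinewood Village Apartments shooting,WA,2013-04-21
Santa Monica College shooting,CA,2013-06-07
Todel Apartments shooting,FL,2013-07-26
The Washington Navy Yard shooting,DC,2013-09-16
Cedarville Rancheria Tribal Office shooting,CA,2014-02-20
Santa Barbara County shooting,CA,2014-05-23
Marysville-Pilchuck High School shooting,WA,2014-10-24
Emanuel African Methodist Episcopal Church shooting,SC,2015-06-17
Recruiting and Naval Reserve centers shooting,TN,2015-07-16
Umpqua Community College shooting,OR,2015-10-01
Tennessee Colony campsite shooting,TX,2015-11-15
Inland Regional Center shooting,CA,2015-12-02
Cracker Barrel shooting,MI,2016-02-20
Franklin Avenue cookout shooting,PA,2016-03-09
Pulse nightclub shooting,FL,2016-06-12
Walgreens Parking Lot shooting,NV,2016-06-29
Police protest march shooting,TX,2016-07-07
Cascades Mall Macy's shooting,WA,2016-09-23
Fort Lauderdale-Hollywood International Airport shooting,FL,2017-01-06
Club 66 shooting,MS,2017-02-06
Marathon Savings Bank shooting,WI,2017-03-22
Fiamma office shooting,FL,2017-06-05
Taos and Rio Arriba counties shooting,NM,2017-06-15
Route 91 Harvest festival shooting,NV,2017-10-01
First Baptist Church shooting,TX,2017-11-05
Rancho Tehama Elementary School shooting,CA,2017-11-14
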