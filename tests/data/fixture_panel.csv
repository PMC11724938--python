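id,time,y1,y2,y3,y4,y5,y6,x1,x2,z1,z2
1,1,5.3952485472901435,8.579105488489914,5.5927549295901855,2.7136698514255326,0.1359374442014496,3.633471334625918,0.0,1.1011874952278309,-2.930499057594777,-2.2985301251358337
1,2,4.810825299544522,8.00923580060666,5.458345168618038,0.6713824132193478,-0.10673883788235583,0.6247739556523891,0.0,-0.2781887024786945,-2.3837591620885035,0.5180615088272571
1,3,2.888285447483953,3.4818380759957757,2.60619805192989,NA,NA,NA,1.0,-0.0018273208569398226,-1.9134358120842805,0.9478374976918524
1,4,2.924565241214065,2.8979423105188205,2.6322353555298217,NA,NA,NA,1.0,NA,2.3292168074980655,0.954850502695098
1,5,NA,NA,NA,NA,NA,NA,NA,NA,2.96993300319952,2.341931810281725
1,6,3.5660660207716948,2.282975957040172,2.6425244004912267,4.903953938834321,9.492711358502799,5.68321727424722,NA,-0.9015386887276633,1.6669936743594072,-2.525720691790452
1,7,1.2644780482727662,0.24115576134858155,4.141557859463645,0.7585544019235901,-7.940602226156995,-0.5722630261178032,NA,NA,0.022736231656894645,0.5224940273512568
1,8,1.4641079930091525,0.376860450800764,2.8596406395774796,-1.2590619467021853,-6.504322532767556,-0.5138562029833212,0.0,0.4927321021090966,2.1864478190843792,-2.229661843477228
1,9,6.67655348219723,6.573983096526516,4.670798059621425,-0.20778046086238433,-7.964760822069541,-4.509695569410759,1.0,-1.7291382332276786,-2.5848049298985583,-1.5901730587747966
1,10,3.2171767393001196,4.3853689512210625,3.313941929043877,4.967378987894938,6.218755958455251,3.9917666196827932,1.0,NA,-0.13592792065502568,0.7006004649996016
1,11,NA,NA,NA,NA,NA,NA,NA,NA,0.7240948819453976,2.5498896207006485
1,12,3.8146419639305686,5.457395802107921,2.877714668258271,2.31211619993672,4.158693489852998,2.5488184576770743,NA,0.22797462756224865,1.673685786680041,-0.04505897567009143
2,1,7.822825919199599,12.678788694220524,5.515007614383174,-1.2839118218645376,-7.1885144012868425,-1.229874037540816,1.0,0.7277614059693119,-2.3773012453172413,0.8673143173915068
2,2,5.384047905405784,9.829056403344666,5.7038595325021575,NA,NA,NA,NA,NA,1.7664705187687213,0.8285988913174291
2,3,7.6740714967132435,12.702744238592496,5.734646867452246,4.342288115349589,3.255818311827869,3.0806399038625942,1.0,1.6213606755936727,-2.5585599171683313,1.4030077310952471
2,4,7.5432378008060255,12.43438787239227,7.4260260943170024,-0.4719570406173016,-1.6746578756624744,0.09439438764055336,1.0,0.5428702984938855,-2.2926707991956428,1.6404068868818493
2,5,6.861605203613375,11.656357577981371,6.77921117421374,2.9191426813869077,-2.5228767243165495,-0.3795447785461208,1.0,-0.012083866667577058,-1.311321741355895,0.5235777587874919
2,6,7.011375851665918,10.183338604640106,6.147693866363809,4.153689712358614,3.406547347072012,3.194149486174892,0.0,1.2598143577055483,-2.7879160060334827,-0.4189221807130066
2,7,8.862465008661854,12.503296224654072,6.553263039052801,1.4222879399877542,-8.126736655699286,-3.065050454164046,0.0,1.8219859083810346,0.14748610741515789,-1.6687439117593548
2,8,9.137484256317576,15.427418452494994,9.209227294361387,1.3794087029165025,-1.5976037158371643,-0.10294187286230927,1.0,2.404403797909714,-2.462476256396559,2.4776612318310436
2,9,NA,NA,NA,-3.5404136432207602,-6.582282476760916,-4.3634612947270135,NA,1.4395903204047829,1.13296685725099,1.6556803273017788
2,10,NA,NA,NA,-1.56913413229341,-7.9735653210395885,-1.871553727745647,NA,-0.5960429548655811,0.27362361837603677,-1.3617073873738732
2,11,2.347232020938058,3.5469630117280007,3.6320949967118743,-1.7836567051899486,-2.651092029734015,1.3985708226907618,NA,NA,-2.4046239467974324,2.2365323364741423
2,12,4.535725911488095,4.605117773143184,2.9063856948290603,1.218785585024238,0.4663654652384608,1.5023702443930524,NA,0.5395339768646588,-2.4696654547366945,2.5046601354086615
3,1,-0.26765085978808734,-0.9669583133410764,1.669854731574979,6.262013292606641,7.301985544116104,4.105749185218773,1.0,-1.6056826444241625,-0.37311774586135193,-2.0736461613613946
3,2,3.393539960696881,3.0856951963887354,5.110237315407286,3.6228432133520263,3.778152595187615,4.250285118613321,1.0,0.7262167862562214,1.0250959325344207,0.5924233997218034
3,3,NA,NA,NA,2.6321647190328217,2.3503648493779696,3.251696744420853,0.0,NA,2.242303037048658,1.2824519036867548
3,4,NA,NA,NA,NA,NA,NA,NA,NA,1.1448759972418596,2.6478705335420125
3,5,5.71339757430755,5.718088436970148,3.6674037647746873,NA,NA,NA,1.0,NA,-0.5220259774605926,-1.7201688331111873
3,6,1.5659467609888134,2.2079314225835045,1.5404503107851333,4.902387061868742,5.323406820361187,3.331261330654901,0.0,0.17121205360621258,1.1946785115832803,-2.7764503452863956
3,7,NA,NA,NA,4.724072719742731,6.416774812187384,3.167205015797226,1.0,0.29373802013743083,2.9133656730502118,-1.8861379293657683
3,8,3.1488286634053697,2.9869633572154166,4.355374201018488,NA,NA,NA,NA,NA,1.9519160316747524,1.3453495075994013
3,9,NA,NA,NA,-2.0667041881273014,-7.755672198665739,0.8686556685438336,NA,0.20910694511276637,-0.106765349933716,2.4447942526929793
3,10,NA,NA,NA,-3.0198506576207462,-10.25506312087523,-2.5694495252714957,1.0,2.1817970115011285,0.47203489616810224,2.7123714643137617
3,11,NA,NA,NA,0.11024872513274159,-1.4641751628415935,-0.8453911388131936,NA,NA,-1.3830181188604262,0.5768838536401981
3,12,4.235265509233427,4.565577455728655,3.815055018111145,NA,NA,NA,NA,NA,2.5446613431626215,2.358373916448792
4,1,2.7024205124279486,2.2254749385547714,2.0759078278977303,0.32363045476306473,-3.9625682255949375,0.42437830460305426,NA,-2.382795567465574,1.040586976477318,-0.6791812495143823
4,2,6.984670011522826,8.694526466988904,3.7930006659017126,1.9811078439138226,1.71745942603592,1.2963113034485454,1.0,0.04520244758532567,1.1873485389295917,-2.7919092424548593
4,3,NA,NA,NA,4.4994334795248685,5.347700617068246,4.4798851801596795,1.0,-0.007736303339008813,0.030719687591224343,-1.1510170043989327
4,4,NA,NA,NA,4.719121151677036,7.846472809899932,6.592075058790914,NA,NA,-1.9052298165808403,0.24775716391055536
4,5,3.9068397403717072,5.697753707333331,3.815903056113576,NA,NA,NA,1.0,NA,-0.22721337641699257,1.5019272799730263
4,6,5.0233615966322605,3.6209591681985698,3.1848384014652082,7.919877930695246,12.247545289927968,7.682349180365569,0.0,-0.5444444218739963,-2.5155083401820377,-2.413312238302326
4,7,1.846071800344455,2.52303012928767,2.0813900457066947,3.574851430883667,5.902609242353682,6.598538870469707,1.0,NA,-2.865795809365863,2.4708374791938494
4,8,2.8447904359645353,6.979629005449121,2.551717233217459,NA,NA,NA,0.0,2.75997338332653,-1.7321847471217953,1.4398847836481865
4,9,3.7991503045885118,3.867414364810087,3.476791881445141,2.3670649271889976,5.153809377932273,5.034561823583823,0.0,0.9300827465837477,0.254715581921539,-0.9636818044656232
4,10,4.320568720444162,4.3249023333238314,2.204373238737612,4.926717035975864,6.6380254009557484,4.563324857244826,1.0,-1.3966412031712994,1.6396160771429757,-1.8307820722039978
4,11,6.436520902606432,5.6456986168815195,6.490089751473361,1.0682160661515072,-1.9756386168972946,0.8789734664930553,1.0,1.8235195966350757,1.9946861780297143,-2.6440555342131487
4,12,NA,NA,NA,-3.1708051714402252,-7.465346756915092,-3.88936898065249,NA,-0.5318159006899956,2.352600347437253,0.7186443498102051
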