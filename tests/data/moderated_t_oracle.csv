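"","coef","t","p","s2","s2post"
"sp0"," 1.627965403943131"," 3.112083233388096","0.009890272750076003","0.8988519163357307","0.818114705102299"
"sp1"," 0.878482722270951"," 3.817885810860450","0.002854302738340219","0.0925149088774297","0.158287581117096"
"sp2","-0.289440396835052","-0.558049879143015","0.587989770660917843","0.8819255061845074","0.804263791121951"
"sp3"," 1.418875927425897"," 1.574928981476120","0.143579977044073825","2.8644554404814060","2.426571849244094"
"sp4"," 0.972946182466593"," 5.124925835705159","0.000331071366564611","0.0307592922023620","0.107752841220825"
"sp5"," 0.217610975879485"," 1.045014876676525","0.318440539748612583","0.0575077561233962","0.129641160691206"
"sp6"," 1.224564983065220"," 2.644473349758596","0.022812844668610815","0.6825066952671752","0.641078994617449"
"sp7"," 0.194397293905175"," 0.495963622288012","0.629681745232069212","0.4603786799249184","0.459311212456710"
"sp8"," 0.393981868458314"," 0.760923116038086","0.462705464398763366","0.8785337196910997","0.801488285711166"
"sp9"," 0.654215615162326"," 1.430241268562871","0.180437181156844567","0.6635074849911444","0.625531904308473"
"sp10"," 0.812421805841525"," 1.029288633258606","0.325448509354640980","2.1752338621155500","1.862580506126678"
"sp11","-0.709227208933953","-0.659886098356806","0.522905520863560791","4.1194019524138774","3.453496993525638"
"sp12","-0.697597606326062","-1.610055920345891","0.135688412820694659","0.5849490113657541","0.561247354253775"
"sp13","-0.666476444531905","-0.762245017311456","0.461947965402243144","2.6922233317890152","2.285633983456898"
"sp14","-1.055815995084833","-1.381428885611191","0.194565578929534105","2.0332658867892830","1.746407838878267"
"sp15","-0.375229219947522","-1.109174857677054","0.291018775715229605","0.3172055359055228","0.342152353348879"
"sp16","-0.809698135013392","-1.750875925650667","0.107770244703148763","0.6804354018287195","0.639384051213160"
"sp17","-0.543685245010092","-1.506609708321868","0.160081807835881634","0.3748607929358981","0.389331761061910"
"sp18"," 0.887025495899744"," 0.697073060527433","0.500226080339484680","5.8150825338590399","4.841075674528170"
"sp19","-0.567096130998945","-0.830328075202199","0.424010818315879057","1.6033044621765686","1.394569578197345"
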