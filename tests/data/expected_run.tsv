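set_id	category	n_detected	median_rank	ks_statistic	p_value	fdr	detected_members	tie_flag
large_001	metabolite_producers	51	0.09979226642	0.2131287298	0.1171452326	0.4685809302	100050,100101,100110,100106,100114,100095,100066,100104,100017,100067,100100,100072,100027,100055,100008,100062,100047,100073,100071,100026,100065,100053,100063,100046,100054,100045,100001,100069,100070,100080,100079,100043,100059,100077,100004,100030,100082,100023,100102,100075,100024,100012,100084,100033,100005,100010,100011,100003,100058,100002,100036	False
medium_003	published_associations	38	0.01556111482	0.1553273427	0.4983439204	0.8221582928	100085,100066,100014,100100,100021,100067,100108,100051,100048,100063,100094,100004,100061,100006,100040,100091,100079,100076,100075,100113,100083,100022,100099,100065,100030,100002,100026,100070,100071,100096,100052,100119,100045,100074,100046,100059,100035,100092	False
medium_001	metabolite_producers	38	-0.005278062797	0.1412066752	0.6166187196	0.8221582928	100061,100084,100049,100101,100027,100013,100063,100004,100107,100050,100056,100078,100098,100099,100001,100090,100058,100035,100093,100030,100076,100014,100041,100113,100003,100097,100119,100070,100002,100118,100088,100028,100055,100095,100068,100029,100057,100064	False
medium_002	health_disease	45	0.01779311853	0.09333333333	0.9500673033	0.9500673033	100030,100045,100120,100087,100029,100098,100059,100038,100003,100054,100108,100072,100083,100013,100024,100081,100093,100113,100016,100096,100043,100104,100092,100065,100055,100097,100086,100025,100039,100037,100076,100064,100095,100051,100090,100005,100062,100032,100052,100111,100023,100047,100071,100048,100012	False
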