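subject_id,gold,MDCTA
s1,1,1
s2,1,1
s3,1,1
s4,1,1
s5,1,1
s6,1,1
s7,1,1
s8,1,1
s9,1,1
s10,1,1
s11,1,1
s12,1,1
s13,1,1
s14,1,1
s15,1,1
s16,1,1
s17,1,1
s18,1,1
s19,1,1
s20,1,1
s21,1,1
s22,1,1
s23,1,1
s24,1,1
s25,1,1
s26,1,1
s27,1,1
s28,1,1
s29,1,1
s30,1,1
s31,1,1
s32,1,1
s33,1,1
s34,1,1
s35,1,1
s36,1,1
s37,1,1
s38,1,1
s39,1,1
s40,1,1
s41,1,1
s42,1,1
s43,1,1
s44,1,1
s45,1,1
s46,1,1
s47,1,1
s48,1,1
s49,1,1
s50,1,1
s51,1,1
s52,1,1
s53,1,1
s54,1,1
s55,1,1
s56,1,1
s57,1,1
s58,1,1
s59,1,1
s60,1,1
s61,1,1
s62,1,1
s63,1,1
s64,1,1
s65,1,1
s66,1,1
s67,1,1
s68,1,1
s69,1,1
s70,1,1
s71,1,1
s72,1,1
s73,1,1
s74,1,1
s75,1,1
s76,1,1
s77,1,1
s78,1,1
s79,1,1
s80,1,1
s81,1,1
s82,1,1
s83,1,1
s84,1,1
s85,1,1
s86,1,1
s87,1,1
s88,1,1
s89,1,1
s90,1,1
s91,1,1
s92,1,1
s93,1,1
s94,1,1
s95,1,1
s96,1,1
s97,1,1
s98,1,1
s99,1,1
s100,1,1
s101,1,1
s102,1,1
s103,1,1
s104,1,1
s105,1,1
s106,1,1
s107,1,1
s108,1,1
s109,1,1
s110,1,1
s111,1,1
s112,1,1
s113,1,1
s114,1,1
s115,1,1
s116,1,1
s117,1,1
s118,1,1
s119,1,1
s120,1,1
s121,1,1
s122,1,1
s123,1,1
s124,1,1
s125,1,1
s126,1,1
s127,1,1
s128,1,1
s129,1,1
s130,1,1
s131,1,1
s132,1,1
s133,1,1
s134,1,1
s135,1,1
s136,1,1
s137,1,1
s138,1,1
s139,1,1
s140,1,1
s141,1,0
s142,1,0
s143,1,0
s144,1,0
s145,1,0
s146,1,0
s147,1,0
s148,1,0
s149,1,0
s150,1,0
s151,1,0
s152,1,0
s153,1,0
s154,1,0
s155,1,0
s156,1,0
s157,1,0
s158,1,0
s159,1,0
s160,1,0
s161,1,0
s162,1,0
s163,1,0
s164,1,0
s165,0,1
s166,0,1
s167,0,1
s168,0,1
s169,0,1
s170,0,1
s171,0,1
s172,0,1
s173,0,1
s174,0,1
s175,0,1
s176,0,1
s177,0,1
s178,0,0
s179,0,0
s180,0,0
s181,0,0
s182,0,0
s183,0,0
s184,0,0
s185,0,0
s186,0,0
s187,0,0
s188,0,0
s189,0,0
s190,0,0
s191,0,0
s192,0,0
s193,0,0
s194,0,0
s195,0,0
s196,0,0
s197,0,0
s198,0,0
s199,0,0
s200,0,0
s201,0,0
s202,0,0
s203,0,0
s204,0,0
s205,0,0
s206,0,0
s207,0,0
s208,0,0
s209,0,0
s210,0,0
s211,0,0
s212,0,0
s213,0,0
s214,0,0
s215,0,0
s216,0,0
s217,0,0
s218,0,0
s219,0,0
s220,0,0
s221,0,0
s222,0,0
s223,0,0
s224,0,0
s225,0,0
s226,0,0
s227,0,0
s228,0,0
s229,0,0
s230,0,0
s231,0,0
s232,0,0
s233,0,0
s234,0,0
s235,0,0
s236,0,0
s237,0,0
s238,0,0
s239,0,0
s240,0,0
s241,0,0
s242,0,0
s243,0,0
s244,0,0
s245,0,0
s246,0,0
s247,0,0
s248,0,0
s249,0,0
s250,0,0
s251,0,0
s252,0,0
s253,0,0
s254,0,0
s255,0,0
s256,0,0
s257,0,0
s258,0,0
s259,0,0
s260,0,0
s261,0,0
s262,0,0
s263,0,0
s264,0,0
s265,0,0
s266,0,0
s267,0,0
s268,0,0
s269,0,0
s270,0,0
s271,0,0
s272,0,0
s273,0,0
s274,0,0
s275,0,0
s276,0,0
s277,0,0
s278,0,0
s279,0,0
s280,0,0
s281,0,0
s282,0,0
s283,0,0
s284,0,0
s285,0,0
s286,0,0
s287,0,0
s288,0,0
s289,0,0
s290,0,0
s291,0,0
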