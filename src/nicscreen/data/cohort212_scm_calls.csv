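sample_id,classification,sex
e001,euploid,XX
e002,aneuploid,XY
e003,aneuploid,XX
e004,euploid,XY
e005,aneuploid,XX
e006,aneuploid,XY
e007,euploid,XX
e008,aneuploid,XY
e009,aneuploid,XX
e010,euploid,XY
e011,aneuploid,XX
e012,aneuploid,XY
e013,euploid,XX
e014,aneuploid,XY
e015,aneuploid,XX
e016,aneuploid,XY
e017,euploid,XX
e018,euploid,XY
e019,aneuploid,XX
e020,euploid,XY
e021,euploid,XX
e022,aneuploid,XY
e023,euploid,XX
e024,euploid,XY
e025,aneuploid,XX
e026,euploid,XY
e027,euploid,XX
e028,aneuploid,XY
e029,euploid,XX
e030,euploid,XY
e031,aneuploid,XX
e032,euploid,XY
e033,euploid,XX
e034,aneuploid,XY
e035,euploid,XX
e036,euploid,XY
e037,aneuploid,XX
e038,euploid,XY
e039,euploid,XX
e040,aneuploid,XY
e041,euploid,XX
e042,euploid,XY
e043,aneuploid,XX
e044,euploid,XY
e045,euploid,XX
e046,aneuploid,XY
e047,euploid,XX
e048,euploid,XY
e049,aneuploid,XX
e050,euploid,XY
e051,euploid,XX
e052,aneuploid,XY
e053,euploid,XX
e054,euploid,XY
e055,aneuploid,XX
e056,euploid,XY
e057,euploid,XX
e058,aneuploid,XY
e059,euploid,XX
e060,euploid,XY
e061,aneuploid,XX
e062,euploid,XY
e063,euploid,XX
e064,aneuploid,XY
e065,euploid,XX
e066,euploid,XY
e067,aneuploid,XX
e068,euploid,XY
e069,euploid,XX
e070,aneuploid,XY
e071,euploid,XX
e072,euploid,XY
e073,aneuploid,XX
e074,euploid,XY
e075,euploid,XX
e076,aneuploid,XY
e077,euploid,XX
e078,euploid,XY
e079,aneuploid,XX
e080,euploid,XY
e081,euploid,XX
e082,aneuploid,XY
e083,euploid,XX
e084,euploid,XY
e085,aneuploid,XX
e086,euploid,XY
e087,euploid,XX
e088,aneuploid,XY
e089,euploid,XX
e090,euploid,XY
e091,aneuploid,XX
e092,euploid,XY
e093,euploid,XX
e094,aneuploid,XY
e095,euploid,XX
e096,euploid,XX
e097,euploid,XX
e098,aneuploid,XY
e099,aneuploid,XX
e100,euploid,XY
e101,aneuploid,XX
e102,aneuploid,XY
e103,euploid,XX
e104,aneuploid,XY
e105,aneuploid,XX
e106,euploid,XY
e107,aneuploid,XX
e108,aneuploid,XY
e109,euploid,XX
e110,aneuploid,XY
e111,aneuploid,XX
e112,euploid,XY
e113,aneuploid,XX
e114,aneuploid,XY
e115,aneuploid,XX
e116,euploid,XY
e117,euploid,XX
e118,aneuploid,XY
e119,euploid,XX
e120,euploid,XY
e121,aneuploid,XX
e122,euploid,XY
e123,euploid,XX
e124,aneuploid,XY
e125,euploid,XX
e126,euploid,XY
e127,aneuploid,XX
e128,euploid,XY
e129,euploid,XX
e130,aneuploid,XY
e131,euploid,XX
e132,euploid,XY
e133,aneuploid,XX
e134,euploid,XY
e135,euploid,XX
e136,aneuploid,XY
e137,euploid,XX
e138,euploid,XY
e139,aneuploid,XX
e140,euploid,XY
e141,euploid,XX
e142,aneuploid,XY
e143,euploid,XX
e144,euploid,XY
e145,aneuploid,XX
e146,euploid,XY
e147,euploid,XX
e148,aneuploid,XY
e149,euploid,XX
e150,euploid,XY
e151,aneuploid,XX
e152,euploid,XY
e153,euploid,XX
e154,aneuploid,XY
e155,euploid,XX
e156,euploid,XY
e157,aneuploid,XX
e158,euploid,XY
e159,euploid,XX
e160,aneuploid,XY
e161,euploid,XX
e162,euploid,XY
e163,aneuploid,XX
e164,euploid,XY
e165,euploid,XX
e166,aneuploid,XY
e167,euploid,XX
e168,euploid,XY
e169,aneuploid,XX
e170,euploid,XY
e171,euploid,XX
e172,aneuploid,XY
e173,euploid,XX
e174,euploid,XY
e175,aneuploid,XX
e176,euploid,XY
e177,euploid,XX
e178,aneuploid,XY
e179,euploid,XX
e180,euploid,XY
e181,aneuploid,XX
e182,euploid,XY
e183,euploid,XX
e184,aneuploid,XY
e185,euploid,XX
e186,euploid,XY
e187,aneuploid,XX
e188,euploid,XY
e189,euploid,XX
e190,aneuploid,XY
e191,euploid,XX
e192,euploid,XY
e193,aneuploid,XX
e194,euploid,XY
e195,euploid,XX
e196,aneuploid,XY
e197,euploid,XX
e198,euploid,XY
e199,aneuploid,XX
e200,euploid,XY
e201,euploid,XX
e202,aneuploid,XY
e203,euploid,XX
e204,euploid,XY
e205,aneuploid,XX
e206,euploid,XY
e207,euploid,XX
e208,aneuploid,XY
e209,euploid,XX
e210,euploid,XX
e211,aneuploid,XY
e212,euploid,XX
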