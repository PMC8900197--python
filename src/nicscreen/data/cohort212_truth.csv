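sample_id,insemination,classification,sex
e001,IVF,aneuploid,XX
e002,IVF,euploid,XY
e003,IVF,euploid,XX
e004,IVF,aneuploid,XY
e005,IVF,euploid,XX
e006,IVF,euploid,XY
e007,IVF,aneuploid,XX
e008,IVF,euploid,XY
e009,IVF,euploid,XX
e010,IVF,aneuploid,XY
e011,IVF,euploid,XX
e012,IVF,euploid,XY
e013,IVF,aneuploid,XX
e014,IVF,euploid,XY
e015,IVF,euploid,XX
e016,IVF,aneuploid,XY
e017,IVF,euploid,XX
e018,IVF,euploid,XY
e019,IVF,aneuploid,XX
e020,IVF,euploid,XY
e021,IVF,euploid,XX
e022,IVF,aneuploid,XY
e023,IVF,euploid,XX
e024,IVF,euploid,XY
e025,IVF,aneuploid,XX
e026,IVF,euploid,XY
e027,IVF,euploid,XX
e028,IVF,aneuploid,XY
e029,IVF,euploid,XX
e030,IVF,euploid,XY
e031,IVF,aneuploid,XX
e032,IVF,euploid,XY
e033,IVF,euploid,XX
e034,IVF,aneuploid,XY
e035,IVF,euploid,XX
e036,IVF,euploid,XY
e037,IVF,aneuploid,XX
e038,IVF,euploid,XY
e039,IVF,euploid,XX
e040,IVF,aneuploid,XY
e041,IVF,euploid,XX
e042,IVF,euploid,XY
e043,IVF,aneuploid,XX
e044,IVF,euploid,XY
e045,IVF,euploid,XX
e046,IVF,aneuploid,XY
e047,IVF,euploid,XX
e048,IVF,euploid,XY
e049,IVF,aneuploid,XX
e050,IVF,euploid,XY
e051,IVF,euploid,XX
e052,IVF,aneuploid,XY
e053,IVF,euploid,XX
e054,IVF,euploid,XY
e055,IVF,aneuploid,XX
e056,IVF,euploid,XY
e057,IVF,euploid,XX
e058,IVF,aneuploid,XY
e059,IVF,euploid,XX
e060,IVF,euploid,XY
e061,IVF,aneuploid,XX
e062,IVF,euploid,XY
e063,IVF,euploid,XX
e064,IVF,aneuploid,XY
e065,IVF,euploid,XX
e066,IVF,euploid,XY
e067,IVF,aneuploid,XX
e068,IVF,euploid,XY
e069,IVF,euploid,XX
e070,IVF,aneuploid,XY
e071,IVF,euploid,XX
e072,IVF,euploid,XY
e073,IVF,aneuploid,XX
e074,IVF,euploid,XY
e075,IVF,euploid,XX
e076,IVF,aneuploid,XY
e077,IVF,euploid,XX
e078,IVF,euploid,XY
e079,IVF,aneuploid,XX
e080,IVF,euploid,XY
e081,IVF,euploid,XX
e082,IVF,aneuploid,XY
e083,IVF,euploid,XX
e084,IVF,euploid,XY
e085,IVF,aneuploid,XX
e086,IVF,euploid,XY
e087,IVF,euploid,XX
e088,IVF,aneuploid,XY
e089,IVF,euploid,XX
e090,IVF,euploid,XY
e091,IVF,aneuploid,XX
e092,IVF,euploid,XY
e093,IVF,euploid,XX
e094,IVF,aneuploid,XY
e095,IVF,euploid,XX
e096,IVF,euploid,XY
e097,ICSI,aneuploid,XX
e098,ICSI,euploid,XY
e099,ICSI,euploid,XX
e100,ICSI,aneuploid,XY
e101,ICSI,euploid,XX
e102,ICSI,euploid,XY
e103,ICSI,aneuploid,XX
e104,ICSI,euploid,XY
e105,ICSI,euploid,XX
e106,ICSI,aneuploid,XY
e107,ICSI,euploid,XX
e108,ICSI,euploid,XY
e109,ICSI,aneuploid,XX
e110,ICSI,euploid,XY
e111,ICSI,euploid,XX
e112,ICSI,aneuploid,XY
e113,ICSI,euploid,XX
e114,ICSI,euploid,XY
e115,ICSI,aneuploid,XX
e116,ICSI,euploid,XY
e117,ICSI,euploid,XX
e118,ICSI,aneuploid,XY
e119,ICSI,euploid,XX
e120,ICSI,euploid,XY
e121,ICSI,aneuploid,XX
e122,ICSI,euploid,XY
e123,ICSI,euploid,XX
e124,ICSI,aneuploid,XY
e125,ICSI,euploid,XX
e126,ICSI,euploid,XY
e127,ICSI,aneuploid,XX
e128,ICSI,euploid,XY
e129,ICSI,euploid,XX
e130,ICSI,aneuploid,XY
e131,ICSI,euploid,XX
e132,ICSI,euploid,XY
e133,ICSI,aneuploid,XX
e134,ICSI,euploid,XY
e135,ICSI,euploid,XX
e136,ICSI,aneuploid,XY
e137,ICSI,euploid,XX
e138,ICSI,euploid,XY
e139,ICSI,aneuploid,XX
e140,ICSI,euploid,XY
e141,ICSI,euploid,XX
e142,ICSI,aneuploid,XY
e143,ICSI,euploid,XX
e144,ICSI,euploid,XY
e145,ICSI,aneuploid,XX
e146,ICSI,euploid,XY
e147,ICSI,euploid,XX
e148,ICSI,aneuploid,XY
e149,ICSI,euploid,XX
e150,ICSI,euploid,XY
e151,ICSI,aneuploid,XX
e152,ICSI,euploid,XY
e153,ICSI,euploid,XX
e154,ICSI,aneuploid,XY
e155,ICSI,euploid,XX
e156,ICSI,euploid,XY
e157,ICSI,aneuploid,XX
e158,ICSI,euploid,XY
e159,ICSI,euploid,XX
e160,ICSI,aneuploid,XY
e161,ICSI,euploid,XX
e162,ICSI,euploid,XY
e163,ICSI,aneuploid,XX
e164,ICSI,euploid,XY
e165,ICSI,euploid,XX
e166,ICSI,aneuploid,XY
e167,ICSI,euploid,XX
e168,ICSI,euploid,XY
e169,ICSI,aneuploid,XX
e170,ICSI,euploid,XY
e171,ICSI,euploid,XX
e172,ICSI,aneuploid,XY
e173,ICSI,euploid,XX
e174,ICSI,euploid,XY
e175,ICSI,aneuploid,XX
e176,ICSI,euploid,XY
e177,ICSI,euploid,XX
e178,ICSI,aneuploid,XY
e179,ICSI,euploid,XX
e180,ICSI,euploid,XY
e181,ICSI,aneuploid,XX
e182,ICSI,euploid,XY
e183,ICSI,euploid,XX
e184,ICSI,aneuploid,XY
e185,ICSI,euploid,XX
e186,ICSI,euploid,XY
e187,ICSI,aneuploid,XX
e188,ICSI,euploid,XY
e189,ICSI,euploid,XX
e190,ICSI,aneuploid,XY
e191,ICSI,euploid,XX
e192,ICSI,euploid,XY
e193,ICSI,aneuploid,XX
e194,ICSI,euploid,XY
e195,ICSI,euploid,XX
e196,ICSI,aneuploid,XY
e197,ICSI,euploid,XX
e198,ICSI,euploid,XY
e199,ICSI,aneuploid,XX
e200,ICSI,euploid,XY
e201,ICSI,euploid,XX
e202,ICSI,aneuploid,XY
e203,ICSI,euploid,XX
e204,ICSI,euploid,XY
e205,ICSI,aneuploid,XX
e206,ICSI,euploid,XY
e207,ICSI,euploid,XX
e208,ICSI,aneuploid,XY
e209,ICSI,euploid,XX
e210,ICSI,euploid,XY
e211,ICSI,aneuploid,XX
e212,ICSI,euploid,XY
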