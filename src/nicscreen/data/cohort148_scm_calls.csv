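sample_id,classification
t001,euploid
t002,euploid
t003,aneuploid
t004,aneuploid
t005,aneuploid
t006,aneuploid
t007,aneuploid
t008,aneuploid
t009,aneuploid
t010,aneuploid
t011,aneuploid
t012,aneuploid
t013,aneuploid
t014,aneuploid
t015,aneuploid
t016,aneuploid
t017,aneuploid
t018,aneuploid
t019,aneuploid
t020,aneuploid
t021,aneuploid
t022,aneuploid
t023,aneuploid
t024,aneuploid
t025,aneuploid
t026,aneuploid
t027,aneuploid
t028,aneuploid
t029,aneuploid
t030,aneuploid
t031,aneuploid
t032,aneuploid
t033,aneuploid
t034,aneuploid
t035,aneuploid
t036,aneuploid
t037,aneuploid
t038,aneuploid
t039,euploid
t040,euploid
t041,euploid
t042,euploid
t043,euploid
t044,euploid
t045,euploid
t046,euploid
t047,euploid
t048,euploid
t049,euploid
t050,euploid
t051,euploid
t052,euploid
t053,euploid
t054,euploid
t055,euploid
t056,euploid
t057,euploid
t058,euploid
t059,euploid
t060,euploid
t061,euploid
t062,euploid
t063,euploid
t064,euploid
t065,euploid
t066,euploid
t067,euploid
t068,euploid
t069,euploid
t070,euploid
t071,euploid
t072,euploid
t073,euploid
t074,euploid
t075,euploid
t076,euploid
t077,euploid
t078,euploid
t079,euploid
t080,euploid
t081,euploid
t082,euploid
t083,euploid
t084,euploid
t085,euploid
t086,euploid
t087,euploid
t088,euploid
t089,euploid
t090,euploid
t091,euploid
t092,aneuploid
t093,aneuploid
t094,aneuploid
t095,aneuploid
t096,aneuploid
t097,aneuploid
t098,aneuploid
t099,aneuploid
t100,aneuploid
t101,aneuploid
t102,aneuploid
t103,aneuploid
t104,aneuploid
t105,aneuploid
t106,aneuploid
t107,aneuploid
t108,aneuploid
t109,aneuploid
t110,aneuploid
t111,aneuploid
t112,aneuploid
t113,aneuploid
t114,aneuploid
t115,aneuploid
t116,aneuploid
t117,aneuploid
t118,aneuploid
t119,euploid
t120,euploid
t121,euploid
t122,euploid
t123,euploid
t124,euploid
t125,euploid
t126,euploid
t127,euploid
t128,euploid
t129,euploid
t130,euploid
t131,euploid
t132,euploid
t133,euploid
t134,euploid
t135,euploid
t136,euploid
t137,euploid
t138,euploid
t139,euploid
t140,euploid
t141,euploid
t142,euploid
t143,euploid
t144,euploid
t145,euploid
t146,euploid
t147,euploid
t148,euploid
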