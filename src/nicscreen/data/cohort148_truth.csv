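sample_id,reference,classification
t001,ICM,aneuploid
t002,ICM,aneuploid
t003,ICM,aneuploid
t004,ICM,aneuploid
t005,ICM,aneuploid
t006,ICM,aneuploid
t007,ICM,aneuploid
t008,ICM,aneuploid
t009,ICM,aneuploid
t010,ICM,aneuploid
t011,ICM,aneuploid
t012,ICM,aneuploid
t013,ICM,aneuploid
t014,ICM,aneuploid
t015,ICM,aneuploid
t016,ICM,aneuploid
t017,ICM,aneuploid
t018,ICM,aneuploid
t019,ICM,aneuploid
t020,ICM,aneuploid
t021,ICM,aneuploid
t022,ICM,aneuploid
t023,ICM,aneuploid
t024,ICM,aneuploid
t025,ICM,aneuploid
t026,ICM,aneuploid
t027,ICM,aneuploid
t028,ICM,aneuploid
t029,ICM,aneuploid
t030,ICM,euploid
t031,ICM,euploid
t032,ICM,euploid
t033,ICM,euploid
t034,ICM,euploid
t035,ICM,euploid
t036,ICM,euploid
t037,ICM,euploid
t038,ICM,euploid
t039,ICM,euploid
t040,ICM,euploid
t041,ICM,euploid
t042,ICM,euploid
t043,ICM,euploid
t044,ICM,euploid
t045,ICM,euploid
t046,ICM,euploid
t047,ICM,euploid
t048,ICM,euploid
t049,ICM,euploid
t050,ICM,euploid
t051,ICM,euploid
t052,ICM,euploid
t053,ICM,euploid
t054,ICM,euploid
t055,ICM,euploid
t056,ICM,euploid
t057,ICM,euploid
t058,ICM,euploid
t059,ICM,euploid
t060,ICM,euploid
t061,ICM,euploid
t062,ICM,euploid
t063,ICM,euploid
t064,ICM,euploid
t065,ICM,euploid
t066,ICM,euploid
t067,ICM,euploid
t068,ICM,euploid
t069,ICM,euploid
t070,ICM,euploid
t071,ICM,euploid
t072,ICM,euploid
t073,ICM,euploid
t074,ICM,euploid
t075,ICM,euploid
t076,ICM,euploid
t077,ICM,euploid
t078,ICM,euploid
t079,ICM,euploid
t080,ICM,euploid
t081,ICM,euploid
t082,ICM,euploid
t083,ICM,euploid
t084,ICM,euploid
t085,ICM,euploid
t086,ICM,euploid
t087,ICM,euploid
t088,ICM,euploid
t089,ICM,euploid
t090,WB,aneuploid
t091,WB,aneuploid
t092,WB,aneuploid
t093,WB,aneuploid
t094,WB,aneuploid
t095,WB,aneuploid
t096,WB,aneuploid
t097,WB,aneuploid
t098,WB,aneuploid
t099,WB,aneuploid
t100,WB,aneuploid
t101,WB,aneuploid
t102,WB,aneuploid
t103,WB,aneuploid
t104,WB,aneuploid
t105,WB,aneuploid
t106,WB,aneuploid
t107,WB,aneuploid
t108,WB,euploid
t109,WB,euploid
t110,WB,euploid
t111,WB,euploid
t112,WB,euploid
t113,WB,euploid
t114,WB,euploid
t115,WB,euploid
t116,WB,euploid
t117,WB,euploid
t118,WB,euploid
t119,WB,euploid
t120,WB,euploid
t121,WB,euploid
t122,WB,euploid
t123,WB,euploid
t124,WB,euploid
t125,WB,euploid
t126,WB,euploid
t127,WB,euploid
t128,WB,euploid
t129,WB,euploid
t130,WB,euploid
t131,WB,euploid
t132,WB,euploid
t133,WB,euploid
t134,WB,euploid
t135,WB,euploid
t136,WB,euploid
t137,WB,euploid
t138,WB,euploid
t139,WB,euploid
t140,WB,euploid
t141,WB,euploid
t142,WB,euploid
t143,WB,euploid
t144,WB,euploid
t145,WB,euploid
t146,WB,euploid
t147,WB,euploid
t148,WB,euploid
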