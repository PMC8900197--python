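sample_id,classification
w001,aneuploid
w002,aneuploid
w003,aneuploid
w004,aneuploid
w005,aneuploid
w006,aneuploid
w007,aneuploid
w008,aneuploid
w009,aneuploid
w010,aneuploid
w011,aneuploid
w012,aneuploid
w013,aneuploid
w014,aneuploid
w015,aneuploid
w016,aneuploid
w017,aneuploid
w018,aneuploid
w019,aneuploid
w020,aneuploid
w021,aneuploid
w022,aneuploid
w023,euploid
w024,euploid
w025,euploid
w026,euploid
w027,euploid
w028,euploid
w029,euploid
w030,euploid
w031,euploid
w032,euploid
w033,euploid
w034,euploid
w035,euploid
w036,euploid
w037,euploid
w038,euploid
w039,euploid
w040,euploid
w041,euploid
w042,euploid
w043,euploid
w044,euploid
w045,euploid
w046,euploid
w047,euploid
w048,euploid
w049,euploid
w050,euploid
w051,euploid
w052,euploid
w053,euploid
w054,euploid
w055,euploid
w056,euploid
w057,euploid
w058,euploid
w059,euploid
w060,euploid
w061,euploid
w062,euploid
w063,euploid
w064,euploid
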