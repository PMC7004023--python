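person_id,wears_correction,ucva_left,ucva_right,cva_left,cva_right,pinhole_left,pinhole_right,bcva_left,bcva_right,age,sex,weight,cluster,residence
wx000,0,6/18,6/18,,,6/6,6/6,,,20,female,1,c00,rural
wx001,0,6/24,6/24,,,6/9,6/9,,,27,male,1,c01,urban
wx002,0,6/36,6/36,,,6/12,6/12,,,34,female,1,c02,urban
wx003,0,6/60,6/60,,,6/6,6/6,,,41,male,1,c03,rural
wx004,0,3/60,3/60,,,6/9,6/9,,,48,female,1,c04,urban
wx005,0,6/18,6/18,,,6/12,6/12,,,55,male,1,c05,urban
wx006,0,6/24,6/24,,,6/6,6/6,,,62,female,1,c06,rural
wx007,0,6/36,6/36,,,6/9,6/9,,,69,male,1,c07,urban
wx008,0,6/60,6/60,,,6/12,6/12,,,76,female,1,c08,urban
wx009,0,3/60,3/60,,,6/6,6/6,,,23,male,1,c09,rural
wx010,0,6/18,6/18,,,6/9,6/9,,,30,female,1,c00,urban
wx011,0,6/24,6/24,,,6/12,6/12,,,37,male,1,c01,urban
wx012,0,6/36,6/36,,,6/6,6/6,,,44,female,1,c02,rural
wx013,0,6/60,6/60,,,6/9,6/9,,,51,male,1,c03,urban
wx014,0,3/60,3/60,,,6/12,6/12,,,58,female,1,c04,urban
wx015,0,6/18,6/18,,,6/6,6/6,,,65,male,1,c05,rural
wx016,0,6/24,6/24,,,6/9,6/9,,,72,female,1,c06,urban
wx017,0,6/36,6/36,,,6/12,6/12,,,79,male,1,c07,urban
wx018,0,6/60,6/60,,,6/6,6/6,,,26,female,1,c08,rural
wx019,0,3/60,3/60,,,6/9,6/9,,,33,male,1,c09,urban
wx020,0,6/18,6/18,,,6/12,6/12,,,40,female,1,c00,urban
wx021,0,6/24,6/24,,,6/6,6/6,,,47,male,1,c01,rural
wx022,0,6/36,6/36,,,6/9,6/9,,,54,female,1,c02,urban
wx023,0,6/60,6/60,,,6/12,6/12,,,61,male,1,c03,urban
wx024,0,3/60,3/60,,,6/6,6/6,,,68,female,1,c04,rural
wx025,0,6/18,6/18,,,6/9,6/9,,,75,male,1,c05,urban
wx026,0,6/24,6/24,,,6/12,6/12,,,22,female,1,c06,urban
wx027,0,6/36,6/36,,,6/6,6/6,,,29,male,1,c07,rural
wx028,0,6/60,6/60,,,6/9,6/9,,,36,female,1,c08,urban
wx029,0,3/60,3/60,,,6/12,6/12,,,43,male,1,c09,urban
wx030,0,6/18,6/18,,,6/6,6/6,,,50,female,1,c00,rural
wx031,0,6/24,6/24,,,6/9,6/9,,,57,male,1,c01,urban
wx032,0,6/36,6/36,,,6/12,6/12,,,64,female,1,c02,urban
wx033,0,6/60,6/60,,,6/6,6/6,,,71,male,1,c03,rural
wx034,0,3/60,3/60,,,6/9,6/9,,,78,female,1,c04,urban
wx035,0,6/18,6/18,,,6/12,6/12,,,25,male,1,c05,urban
wx036,0,6/24,6/24,,,6/6,6/6,,,32,female,1,c06,rural
wx037,0,6/36,6/36,,,6/9,6/9,,,39,male,1,c07,urban
wx038,0,6/60,6/60,,,6/12,6/12,,,46,female,1,c08,urban
wx039,0,3/60,3/60,,,6/6,6/6,,,53,male,1,c09,rural
wx040,0,6/18,6/18,,,6/9,6/9,,,60,female,1,c00,urban
wx041,0,6/24,6/24,,,6/12,6/12,,,67,male,1,c01,urban
wx042,0,6/36,6/36,,,6/6,6/6,,,74,female,1,c02,rural
wx043,0,6/60,6/60,,,6/9,6/9,,,21,male,1,c03,urban
wx044,0,3/60,3/60,,,6/12,6/12,,,28,female,1,c04,urban
wx045,0,6/18,6/18,,,6/6,6/6,,,35,male,1,c05,rural
wx046,0,6/24,6/24,,,6/9,6/9,,,42,female,1,c06,urban
wx047,0,6/36,6/36,,,6/12,6/12,,,49,male,1,c07,urban
wx048,0,6/60,6/60,,,6/6,6/6,,,56,female,1,c08,rural
wx049,0,3/60,3/60,,,6/9,6/9,,,63,male,1,c09,urban
wx050,1,6/6,6/6,6/6,6/6,,,,,70,female,1,c00,urban
wx051,1,6/9,6/9,6/6,6/6,,,,,77,male,1,c01,rural
wx052,1,6/12,6/12,6/6,6/6,,,,,24,female,1,c02,urban
wx053,1,6/6,6/6,6/6,6/6,,,,,31,male,1,c03,urban
wx054,1,6/9,6/9,6/6,6/6,,,,,38,female,1,c04,rural
wx055,1,6/12,6/12,6/6,6/6,,,,,45,male,1,c05,urban
wx056,1,6/6,6/6,6/6,6/6,,,,,52,female,1,c06,urban
wx057,1,6/9,6/9,6/6,6/6,,,,,59,male,1,c07,rural
wx058,1,6/12,6/12,6/6,6/6,,,,,66,female,1,c08,urban
wx059,1,6/6,6/6,6/6,6/6,,,,,73,male,1,c09,urban
wx060,1,6/9,6/9,6/6,6/6,,,,,20,female,1,c00,rural
wx061,1,6/12,6/12,6/6,6/6,,,,,27,male,1,c01,urban
wx062,1,6/6,6/6,6/6,6/6,,,,,34,female,1,c02,urban
wx063,1,6/9,6/9,6/6,6/6,,,,,41,male,1,c03,rural
wx064,1,6/12,6/12,6/6,6/6,,,,,48,female,1,c04,urban
wx065,1,6/6,6/6,6/6,6/6,,,,,55,male,1,c05,urban
wx066,1,6/9,6/9,6/6,6/6,,,,,62,female,1,c06,rural
wx067,1,6/12,6/12,6/6,6/6,,,,,69,male,1,c07,urban
wx068,1,6/6,6/6,6/6,6/6,,,,,76,female,1,c08,urban
wx069,1,6/9,6/9,6/6,6/6,,,,,23,male,1,c09,rural
wx070,1,6/60,6/36,6/18,6/24,6/9,6/12,,,30,female,1,c00,urban
wx071,1,6/60,6/36,6/18,6/24,6/9,6/12,,,37,male,1,c01,urban
wx072,1,6/60,6/36,6/18,6/24,6/9,6/12,,,44,female,1,c02,rural
wx073,1,6/60,6/36,6/18,6/24,6/9,6/12,,,51,male,1,c03,urban
wx074,1,6/60,6/36,6/18,6/24,6/9,6/12,,,58,female,1,c04,urban
wx075,1,6/24,6/36,6/6,6/6,,,,,65,male,1,c05,rural
wx076,1,6/24,6/36,6/9,6/9,,,,,72,female,1,c06,urban
wx077,1,6/24,6/36,6/12,6/12,,,,,79,male,1,c07,urban
wx078,1,6/24,6/36,6/6,6/6,,,,,26,female,1,c08,rural
wx079,1,6/24,6/36,6/9,6/9,,,,,33,male,1,c09,urban
wx080,1,6/24,6/36,6/12,6/12,,,,,40,female,1,c00,urban
wx081,1,6/24,6/36,6/6,6/6,,,,,47,male,1,c01,rural
wx082,1,6/24,6/36,6/9,6/9,,,,,54,female,1,c02,urban
wx083,1,6/24,6/36,6/12,6/12,,,,,61,male,1,c03,urban
wx084,1,6/24,6/36,6/6,6/6,,,,,68,female,1,c04,rural
wx085,1,6/24,6/36,6/9,6/9,,,,,75,male,1,c05,urban
wx086,1,6/24,6/36,6/12,6/12,,,,,22,female,1,c06,urban
wx087,1,6/24,6/36,6/6,6/6,,,,,29,male,1,c07,rural
wx088,1,6/24,6/36,6/9,6/9,,,,,36,female,1,c08,urban
wx089,1,6/24,6/36,6/12,6/12,,,,,43,male,1,c09,urban
wx090,1,6/24,6/36,6/6,6/6,,,,,50,female,1,c00,rural
wx091,1,6/24,6/36,6/9,6/9,,,,,57,male,1,c01,urban
wx092,1,6/24,6/36,6/12,6/12,,,,,64,female,1,c02,urban
wx093,1,6/24,6/36,6/6,6/6,,,,,71,male,1,c03,rural
wx094,1,6/24,6/36,6/9,6/9,,,,,78,female,1,c04,urban
wx095,1,6/24,6/36,6/12,6/12,,,,,25,male,1,c05,urban
wx096,1,6/24,6/36,6/6,6/6,,,,,32,female,1,c06,rural
wx097,1,6/24,6/36,6/9,6/9,,,,,39,male,1,c07,urban
wx098,1,6/24,6/36,6/12,6/12,,,,,46,female,1,c08,urban
wx099,1,6/24,6/36,6/6,6/6,,,,,53,male,1,c09,rural
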