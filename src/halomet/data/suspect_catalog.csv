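name,formula,rt_min,calcd_mz,obsd_mz,error_ppm,fragment_ions,leaves,flowers,fruits,level,phase,previously_reported,has_standard
Cyantraniliprole,C19H14BrClN6O2,9.31,473.0123,473.0126,0.6,284 442,+,+,+,1,parent,True,True
IN-J9Z38,C19H12BrClN6O,11.04,455.0017,455.0022,1.1,350 361 375 398 419,+,+,-,2b,phase_I,True,False
IN-RNU71,C19H13BrN6O2,8.15,437.0356,437.0361,1.1,301 327 406,+,+,-,2b,phase_I,True,False
IN-HGW87,C18H12BrClN6O2,8.30,458.9966,458.9972,1.3,284 442,+,-,-,2b,phase_I,True,False
IN-JSE76,C19H15BrClN5O4,8.40,492.0069,492.0077,1.6,284 461,+,-,-,2b,phase_I,True,False
IN-JCZ38,C19H16BrClN6O3,7.59,491.0228,491.0235,1.3,284 460,+,+,-,2b,phase_I,True,False
IN-MLA84,C18H10BrClN6O,10.27,440.9861,440.9866,1.1,270 284 312 361 405,+,+,+,2b,phase_I,True,False
IN-MYX98,C19H14BrClN6O3,8.44,489.0072,489.0078,1.2,442 471,+,+,-,2b,phase_I,True,False
IN-DBC80,C9H5BrClN3O2,7.77,301.9326,301.9328,0.7,258 284,+,+,+,2b,breakdown,True,False
IN-M2G98,C9H6BrClN4O,7.32,300.9486,300.9486,0.0,,+,+,-,5,breakdown,True,False
TP315,C10H8BrClN4O,7.80,314.9643,314.9644,0.3,284,+,+,-,3,breakdown,False,False
TP316,C10H7BrClN3O2,10.11,315.9483,315.9486,1.0,,+,+,+,5,breakdown,False,False
TP363,C18H11ClN6O,8.99,363.0756,363.0760,1.1,206 234 270 327,+,+,-,3,phase_I,False,False
TP405,C18H9BrN6O,11.51,405.0094,405.0100,1.5,298 326,+,-,-,3,phase_I,False,False
TP423,C18H11BrN6O2,7.79,423.0200,423.0207,1.7,262 289 327 406,+,+,-,3,phase_I,False,False
TP441,C18H10BrClN6O,8.42,440.9861,440.9865,0.9,284 405,+,-,-,3,phase_I,False,False
TP577,C22H18BrClN6O4S,8.67,577.0055,577.0063,1.4,,+,+,-,5,phase_II,False,False
TP619,C24H20BrClN6O7,6.95,619.0338,619.0347,1.5,403 439 457,+,+,+,3,phase_II,False,False
TP633,C25H22BrClN6O7,7.67,633.0495,633.0503,1.3,471,+,-,-,3,phase_II,False,False
TP651a,C25H24BrClN6O8,6.53,651.0600,651.0608,1.2,284 458 471 489,+,+,-,3,phase_II,False,False
TP651b,C25H24BrClN6O8,7.21,651.0600,651.0616,2.5,442 471 489,+,-,-,3,phase_II,False,False
TP654,C25H25BrClN5O9,7.20,654.0597,654.0608,1.7,284 445 461 474 623,+,-,-,3,phase_II,False,False
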