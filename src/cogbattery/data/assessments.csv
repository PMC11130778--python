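name,modality,ambiguous_modality,direction,adaptive_kind,score_min,score_max,calib_mean,calib_sd,calib_median,duration_mean_min,duration_sd_min,trial_seconds,loading_f1,loading_f2,loading_f3,loading_f4,age_sensitive,bounds_modifiable,study_n,study_n_highest,study_pct_highest,study_n_lowest,study_pct_lowest,study_sig_gender,study_sig_education,study_sig_race
Auditory Ace,auditory,False,higher_better,set_size,1,6,2.4,2.1,1,2.9,2.1,4.35,0.503857,0.122702,0.155117,-0.296731,True,unmodifiable_deprecate,112,25,22.3,65,58,True,True,False
Card Shark,visual,False,higher_better,set_size,1,6,1.5,1.0,1,2.4,2.0,3.6,0.560295,0.071172,0.040249,-0.301107,True,unmodifiable_diagnostic,117,3,2.6,72,61.5,True,False,False
Divided Attention,visual,False,lower_better,exposure_duration_ms,32,2048,928.5,718.5,653,2.3,2.3,3.45,-0.099982,-0.107536,-0.13645,0.648114,True,modifiable,210,51,24.3,1,0.5,False,False,False
Double Decision,visual,False,lower_better,exposure_duration_ms,17,3162,1174.6,890.9,869,2.9,1.3,4.35,-0.302018,-0.345077,-0.286697,0.473593,True,modifiable,177,23,12.9,1,0.6,False,False,False
Eye For Detail,visual,False,lower_better,exposure_duration_ms,32,3162,373.4,913.2,162,3.6,1.5,5.4,-0.122413,-0.177566,-0.089855,0.190312,True,none,228,8,3.5,3,1.3,False,False,False
Face Facts,visual,True,higher_better,set_size,1,10,5.5,3.3,4.5,6.1,3.8,9.15,0.301677,0.341475,0.027211,-0.066479,True,modifiable,113,31,27.4,1,0.9,False,False,False
Face To Face,visual,False,lower_better,exposure_duration_ms,100,5623,2243.1,1515.3,1862,3.9,1.6,5.85,-0.132008,-0.288762,-0.125521,0.091978,True,none,188,11,5.9,1,0.5,False,False,False
Fine Tuning,auditory,False,higher_better,similarity,1,12,6.6,2.4,6.9,1.4,2.0,2.1,0.19339,0.389311,-0.13749,-0.08356,True,none,236,1,0.4,5,2.1,False,False,False
Freeze Frame,visual,False,higher_better,similarity,1,7,4.6,2.0,5,4.6,0.8,6.9,-0.131735,0.240563,0.158117,-0.157661,False,unmodifiable_diagnostic,166,40,24.1,16,9.6,True,False,False
Hawk Eye,visual,False,lower_better,exposure_duration_ms,32,8000,1064.1,1140.1,794,2.3,1.1,3.45,-0.310039,-0.337505,-0.143804,0.398793,True,none,253,3,1.2,1,0.4,True,False,False
"Hear, Hear 2",auditory,False,higher_better,similarity,1,16,4.0,3.9,1.4,3.2,1.6,4.8,0.235846,0.047723,0.542699,-0.163235,True,unmodifiable_deprecate,164,1,0.6,77,47,False,False,False
In The Know,auditory,True,higher_better,set_size,1,4,1.9,0.5,1.5,2.2,1.4,3.3,-0.068834,0.020406,0.260689,-0.321159,False,none,112,2,1.8,3,2.7,False,True,False
Juggle Factor,visual,False,higher_better,set_size,1,7,4.0,0.9,4,4.5,2.3,6.75,0.595876,0.212351,0.36232,-0.248625,True,none,146,2,1.4,5,3.4,False,False,True
Memory Grid,auditory,True,higher_better,set_size,1,5,3.2,0.6,3.5,4.5,2.1,6.75,0.236313,0.530412,0.226062,-0.070232,False,none,133,3,2.3,5,3.8,False,False,False
Mental Map,visual,False,higher_better,similarity,1,7,2.6,1.4,2.5,3.8,2.0,5.7,0.415206,0.299156,0.249758,-0.030327,True,none,180,2,1.1,11,6.1,True,False,False
Mind Bender,visual,False,lower_better,exposure_duration_ms,100,5623,1356.7,983.5,1082,2.6,1.0,3.9,-0.03505,-0.072113,-0.384683,0.042763,False,none,117,1,0.9,1,0.9,False,False,True
Mind's Eye,visual,False,higher_better,similarity,1,10,4.4,1.9,4.4,2.9,0.7,4.35,0.157655,0.258577,0.389291,-0.197173,True,none,150,2,1.3,12,8,True,False,False
Mixed Signals,auditory,True,lower_better,exposure_duration_ms,32,3162,382.1,729.0,90,3.2,0.9,4.8,-0.274174,-0.071447,-0.108041,0.502077,True,unmodifiable_diagnostic,161,1,0.6,64,39.8,False,False,False
Optic Flow,visual,False,lower_better,exposure_duration_ms,500,7000,3114.8,1239.7,2896,2.7,4.8,4.05,-0.129046,-0.550209,-0.084751,0.492414,True,none,147,1,0.7,1,0.7,False,False,False
Recognition,visual,False,lower_better,exposure_duration_ms,100,7000,1326.5,1566.8,709.3,3.3,1.4,4.95,-0.225051,-0.581809,0.047476,0.380003,True,none,122,2,1.6,1,0.8,False,False,False
Rhythm Recall,auditory,False,higher_better,set_size,1,4,1.6,0.7,1.5,4.3,1.3,6.45,0.257117,0.006417,0.388292,-0.165549,False,unmodifiable_diagnostic,133,1,0.8,40,30.1,False,False,False
Right Turn,visual,False,lower_better,exposure_duration_ms,500,11585,5027.9,3923.7,3984,4.5,1.6,6.75,-0.117989,-0.1912,-0.312604,0.156221,False,modifiable,129,23,17.8,2,1.6,False,False,False
Scene Crasher,visual,False,higher_better,set_size,1,18,8.2,3.2,7.8,3.6,1.1,5.4,0.643301,0.279054,0.225773,-0.014381,True,none,183,1,0.6,6,3.3,False,False,False
Sound Sweeps,auditory,False,lower_better,speed,20,1000,192.5,209.9,126,2.1,0.8,3.15,-0.156355,0.038414,-0.473407,0.039435,True,none,175,8,4.6,1,0.6,False,False,False
Syllable Stacks,auditory,False,higher_better,set_size,1,6,3.6,0.6,3.5,2.8,0.9,4.2,0.083591,0.5406,0.206336,0.039898,False,none,120,1,0.8,1,0.8,False,False,False
Target Tracker,visual,False,higher_better,set_size,1,6,2.9,1.0,2.9,3.9,1.8,5.85,0.509138,0.203934,0.223545,-0.061977,True,unmodifiable_diagnostic,158,5,3.2,29,18.4,False,False,False
To-Do List Training,auditory,True,higher_better,set_size,1,9,5.6,1.2,5.5,4.5,2.7,6.75,0.065038,0.346688,0.505778,-0.147192,True,none,132,1,0.8,3,2.3,False,False,False
True North,visual,False,higher_better,set_size,1,9,3.3,1.8,2.5,4.3,3.0,6.45,0.465121,0.199453,0.353845,-0.025954,False,unmodifiable_diagnostic,110,3,2.7,25,22.7,True,False,False
Visual Sweeps,visual,False,lower_better,speed,20,900,169.5,161.5,130,2.3,0.6,3.45,-0.146627,-0.095615,-0.538311,0.075673,True,none,164,5,3.1,1,0.6,True,False,False
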