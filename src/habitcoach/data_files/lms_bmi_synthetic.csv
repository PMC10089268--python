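# SYNTHETIC BMI-for-age LMS reference (not a real growth standard).
# Smooth, monotone, order-of-magnitude realistic values for testing.
sex,age_months,L,M,S
female,108,-1.6000,16.000,0.11500
female,109,-1.5960,16.046,0.11530
female,110,-1.5920,16.092,0.11560
female,111,-1.5880,16.138,0.11590
female,112,-1.5840,16.184,0.11620
female,113,-1.5800,16.230,0.11650
female,114,-1.5760,16.276,0.11680
female,115,-1.5720,16.322,0.11710
female,116,-1.5680,16.368,0.11740
female,117,-1.5640,16.414,0.11770
female,118,-1.5600,16.460,0.11800
female,119,-1.5560,16.506,0.11830
female,120,-1.5520,16.552,0.11860
female,121,-1.5480,16.598,0.11890
female,122,-1.5440,16.644,0.11920
female,123,-1.5400,16.690,0.11950
female,124,-1.5360,16.736,0.11980
female,125,-1.5320,16.782,0.12010
female,126,-1.5280,16.828,0.12040
female,127,-1.5240,16.874,0.12070
female,128,-1.5200,16.920,0.12100
female,129,-1.5160,16.966,0.12130
female,130,-1.5120,17.012,0.12160
female,131,-1.5080,17.058,0.12190
female,132,-1.5040,17.104,0.12220
female,133,-1.5000,17.150,0.12250
female,134,-1.4960,17.196,0.12280
female,135,-1.4920,17.242,0.12310
female,136,-1.4880,17.288,0.12340
female,137,-1.4840,17.334,0.12370
female,138,-1.4800,17.380,0.12400
female,139,-1.4760,17.426,0.12430
female,140,-1.4720,17.472,0.12460
female,141,-1.4680,17.518,0.12490
female,142,-1.4640,17.564,0.12520
female,143,-1.4600,17.610,0.12550
female,144,-1.4560,17.656,0.12580
female,145,-1.4520,17.702,0.12610
female,146,-1.4480,17.748,0.12640
female,147,-1.4440,17.794,0.12670
female,148,-1.4400,17.840,0.12700
female,149,-1.4360,17.886,0.12730
female,150,-1.4320,17.932,0.12760
female,151,-1.4280,17.978,0.12790
female,152,-1.4240,18.024,0.12820
female,153,-1.4200,18.070,0.12850
female,154,-1.4160,18.116,0.12880
female,155,-1.4120,18.162,0.12910
male,108,-1.5000,15.800,0.11000
male,109,-1.4970,15.840,0.11025
male,110,-1.4940,15.880,0.11050
male,111,-1.4910,15.920,0.11075
male,112,-1.4880,15.960,0.11100
male,113,-1.4850,16.000,0.11125
male,114,-1.4820,16.040,0.11150
male,115,-1.4790,16.080,0.11175
male,116,-1.4760,16.120,0.11200
male,117,-1.4730,16.160,0.11225
male,118,-1.4700,16.200,0.11250
male,119,-1.4670,16.240,0.11275
male,120,-1.4640,16.280,0.11300
male,121,-1.4610,16.320,0.11325
male,122,-1.4580,16.360,0.11350
male,123,-1.4550,16.400,0.11375
male,124,-1.4520,16.440,0.11400
male,125,-1.4490,16.480,0.11425
male,126,-1.4460,16.520,0.11450
male,127,-1.4430,16.560,0.11475
male,128,-1.4400,16.600,0.11500
male,129,-1.4370,16.640,0.11525
male,130,-1.4340,16.680,0.11550
male,131,-1.4310,16.720,0.11575
male,132,-1.4280,16.760,0.11600
male,133,-1.4250,16.800,0.11625
male,134,-1.4220,16.840,0.11650
male,135,-1.4190,16.880,0.11675
male,136,-1.4160,16.920,0.11700
male,137,-1.4130,16.960,0.11725
male,138,-1.4100,17.000,0.11750
male,139,-1.4070,17.040,0.11775
male,140,-1.4040,17.080,0.11800
male,141,-1.4010,17.120,0.11825
male,142,-1.3980,17.160,0.11850
male,143,-1.3950,17.200,0.11875
male,144,-1.3920,17.240,0.11900
male,145,-1.3890,17.280,0.11925
male,146,-1.3860,17.320,0.11950
male,147,-1.3830,17.360,0.11975
male,148,-1.3800,17.400,0.12000
male,149,-1.3770,17.440,0.12025
male,150,-1.3740,17.480,0.12050
male,151,-1.3710,17.520,0.12075
male,152,-1.3680,17.560,0.12100
male,153,-1.3650,17.600,0.12125
male,154,-1.3620,17.640,0.12150
male,155,-1.3590,17.680,0.12175
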