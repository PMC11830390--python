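gene	segment_type	family	anchor_start	fr1_start	fr1_end	cdr1_start	cdr1_end	fr2_start	fr2_end	cdr2_start	cdr2_end	fr3_start	fr3_end
IGHD1-S1*01	D	IGHD1											
IGHD1-S2*01	D	IGHD1											
IGHD2-S1*01	D	IGHD2											
IGHD2-S2*01	D	IGHD2											
IGHD3-S1*01	D	IGHD3											
IGHD3-S2*01	D	IGHD3											
IGHD4-S1*01	D	IGHD4											
IGHD4-S2*01	D	IGHD4											
IGHJ3-S1*01	J	IGHJ3	12										
IGHJ4-S1*01	J	IGHJ4	9										
IGHJ5-S1*01	J	IGHJ5	15										
IGHJ6-S1*01	J	IGHJ6	18										
IGHV1-S1*01	V	IGHV1	288	0	78	78	102	102	153	153	177	177	288
IGHV1-S2*01	V	IGHV1	288	0	78	78	102	102	153	153	177	177	288
IGHV3-S1*01	V	IGHV3	288	0	78	78	102	102	153	153	177	177	288
IGHV3-S2*01	V	IGHV3	288	0	78	78	102	102	153	153	177	177	288
IGHV3-S3*01	V	IGHV3	288	0	78	78	102	102	153	153	177	177	288
IGHV4-S1*01	V	IGHV4	288	0	78	78	102	102	153	153	177	177	288
IGHV4-S2*01	V	IGHV4	288	0	78	78	102	102	153	153	177	177	288
IGHV5-S1*01	V	IGHV5	288	0	78	78	102	102	153	153	177	177	288
IGHV5-S2*01	V	IGHV5	288	0	78	78	102	102	153	153	177	177	288
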