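category	family	mean_east	sd_east	n_east	mean_west	sd_west	n_west
emo_pos	affective	0.81	3.96	21156	0.52	3.04	21156
emo_neg	affective	29.68	20.76	21156	29.17	20.4	21156
emo_anx	affective	0.08	1.22	21156	0.09	1.34	21156
emo_anger	affective	0.75	4.44	21156	0.68	4.26	21156
emo_sad	affective	28.61	21.32	21156	28.1	20.83	21156
swear	affective	0.19	2.15	21156	0.41	3.31	21156
physical	biological	2.41	9.15	21156	4.22	12.19	21156
health	biological	2.03	8.78	21156	3.5	11.64	21156
mental	biological	1.94	8.68	21156	3.39	11.56	21156
sexual	biological	0.05	0.94	21156	0.12	1.51	21156
death	biological	0.08	1.13	21156	0.14	1.47	21156
family	social	0.23	2.17	21156	0.26	2.29	21156
friend	social	0.18	1.61	21156	0.22	1.75	21156
home	social	0.03	0.64	21156	0.06	0.93	21156
work	social	0.09	1.07	21156	0.11	1.35	21156
past_focus	time	0.86	4.01	21156	1.24	4.81	21156
present_focus	time	19.45	18.67	21156	13.05	17.25	21156
future_focus	time	0.39	2.53	21156	0.4	2.5	21156
visual	perceptual	0.13	1.53	21156	0.25	2.29	21156
auditory	perceptual	0.19	2.08	21156	0.16	2.01	21156
feel	perceptual	1.86	6.48	21156	1.48	5.82	21156
pron_1st	interpersonal	20.61	18.49	21156	20.06	17	21156
pron_2nd	interpersonal	3.43	8.15	21156	3.9	8.86	21156
pron_3rd	interpersonal	0.26	1.97	21156	0.26	1.96	21156
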