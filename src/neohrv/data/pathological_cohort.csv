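patient_id,group,record_length,n_events,mean_event,min_event,max_event,etiology
EGP1,EGP,01:08:29,1,00:03:40,00:03:40,00:03:40,Metabolic
EGP2,EGP,01:09:34,8,00:00:24,00:00:12,00:00:43,HIE
EGP3,EGP,01:10:15,1,00:00:31,00:00:31,00:00:31,Other
EGP4,EGP,00:56:28,4,00:00:16,00:00:07,00:00:22,HIE
EGP5,EGP,01:02:30,3,00:01:45,00:01:18,00:02:00,HIE
EGP6,EGP,01:17:02,4,00:00:12,00:00:08,00:00:16,HIE
EGP7,EGP,01:05:53,1,00:00:50,00:00:50,00:00:50,HIE
EGP8,EGP,00:45:40,3,00:01:28,00:01:19,00:01:40,HIE
EGP9,EGP,01:20:39,1,00:00:29,00:00:29,00:00:29,Other
EGP10,EGP,00:58:22,1,00:01:40,00:01:40,00:01:40,Other
ECP1,ECP,00:48:12,1,00:48:12,00:48:12,00:48:12,Genetic
ECP2,ECP,00:54:31,13,00:01:48,00:00:27,00:09:49,Metabolic
ECP3,ECP,01:04:14,6,00:02:49,00:01:20,00:04:40,Stroke
ECP4,ECP,01:18:36,5,00:00:33,00:00:16,00:00:50,Genetic
ECP5,ECP,01:00:10,3,00:07:54,00:01:56,00:19:45,Other
ECP6,ECP,01:10:02,7,00:01:05,00:00:33,00:02:23,HIE
ECP7,ECP,00:54:06,1,00:10:26,00:10:26,00:10:26,Stroke
ECP8,ECP,01:00:43,10,00:02:53,00:01:19,00:11:04,Other
ECP9,ECP,01:30:08,5,00:00:48,00:00:22,00:01:16,HIE
ECP10,ECP,00:41:16,3,00:03:52,00:00:20,00:10:10,Stroke
ECP11,ECP,01:01:02,8,00:00:52,00:00:26,00:02:01,HIE
ECP12,ECP,01:20:06,3,00:01:58,00:01:19,00:02:31,HIE
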