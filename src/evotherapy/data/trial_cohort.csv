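subject_id,gleason,site_of_metastasis,pre_abiraterone_psa,dose_pct
1001,8 (4+4),Bone; soft tissue,6.06,62
1002,8 (4+4),Bone,58.57,55
1003,9 (5+4),Bone; lymph node,68,42
1005,7 (4+3),Lymph node,95.86,87
1006,8 (4+4),Bone,15.25,23
1007,6 (3+3),Bone,109.4,21
1009,6 (3+3),Bone,13.55,53
1010,7 (3+4),Bone,17.33,45
1011,9 (4+5),Lymph node,2.42,53
1012,8 (4+4),Bone,4.17,21
1014,7 (4+3),Bone,11.83,52
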