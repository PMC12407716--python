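sample_id,organ,processing,replicate,is_blank
root_extract_1,root,extract,1,False
root_extract_2,root,extract,2,False
root_extract_3,root,extract,3,False
root_juice_1,root,juice,1,False
root_juice_2,root,juice,2,False
root_juice_3,root,juice,3,False
seed_extract_1,seed,extract,1,False
seed_extract_2,seed,extract,2,False
seed_extract_3,seed,extract,3,False
seed_juice_1,seed,juice,1,False
seed_juice_2,seed,juice,2,False
seed_juice_3,seed,juice,3,False
blank_1,none,none,1,True
blank_2,none,none,2,True
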