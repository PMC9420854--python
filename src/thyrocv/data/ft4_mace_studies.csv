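study_id,first_author,n_subjects,ft4_positive
gussekloo,Gussekloo,599,true
chaker,Chaker,10318,true
pearce,Pearce,643,false
kannan,Kannan,1365,true
golledge,Golledge,3712,true
groothof,Groothof,6054,true
mueller,Mueller,115,true
evron,Evron,705307,true
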