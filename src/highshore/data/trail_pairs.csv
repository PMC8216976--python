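association_type,species,tide_phase,combination,count
trail_following,E. malaccana,rising,FM,68
trail_following,E. malaccana,rising,MM,26
trail_following,E. malaccana,rising,MF,12
trail_following,E. malaccana,rising,FF,20
trail_following,E. malaccana,falling,FM,38
trail_following,E. malaccana,falling,MM,29
trail_following,E. malaccana,falling,MF,23
trail_following,E. malaccana,falling,FF,30
trail_following,E. radiata,rising,FM,61
trail_following,E. radiata,rising,MM,15
trail_following,E. radiata,rising,MF,14
trail_following,E. radiata,rising,FF,30
trail_following,E. radiata,falling,FM,32
trail_following,E. radiata,falling,MM,25
trail_following,E. radiata,falling,MF,30
trail_following,E. radiata,falling,N,120
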