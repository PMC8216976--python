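association_type,species,tide_phase,combination,count
tower,E. malaccana,before_rising,FM,31
tower,E. malaccana,before_rising,MM,2
tower,E. malaccana,before_rising,MF,3
tower,E. malaccana,before_rising,FF,5
tower,E. malaccana,after_falling,FM,23
tower,E. malaccana,after_falling,MM,17
tower,E. malaccana,after_falling,MF,7
tower,E. malaccana,after_falling,FF,17
tower,E. radiata,before_rising,FM,36
tower,E. radiata,before_rising,MM,2
tower,E. radiata,before_rising,MF,0
tower,E. radiata,before_rising,FF,2
tower,E. radiata,after_falling,FM,25
tower,E. radiata,after_falling,MM,10
tower,E. radiata,after_falling,MF,4
tower,E. radiata,after_falling,FF,4
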