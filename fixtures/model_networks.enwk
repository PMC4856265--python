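((((A:1.2,B:1.2):0.9,((C:0.8,D:0.8):0.8)#H1:0.5::0.5):1,(#H1:0.7::0.5,(E:1.1,F:1.1):0.9):1):0.8,O:1.5);
((((A:1.2,(B:0.6)#H1:0.6::0.7):0.9,((C:0.8,D:0.8):0.8)#H2:0.5::0.5):1,(((#H1:0.9::0.3,F:0.6):0.5,E:1.1):0.9,#H2:0.7::0.5):1):0.8,O:1.5);
(((((A:1.2,(B:0.6)#H1:0.6::0.7):0.9,((C:0.8,D:0.8):0.8)#H2:0.5::0.5):0.5,(E:0.7)#H3:0.9::0.25):0.5,(((#H1:0.9::0.3,F:0.6):0.5,#H3:0.6::0.75):0.9,#H2:0.7::0.5):1):0.8,O:1.5);
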