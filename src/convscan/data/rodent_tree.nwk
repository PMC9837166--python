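(((Osib:0.06,(Dsag:0.045,Jjac:0.045):0.015):0.02475,(Sgal:0.0675,(((Mmer:0.015,Mung:0.015):0.03,((Mcar:0.0045,Mmus:0.0045):0.0075,Mpah:0.012):0.033):0.0075,(Cgri:0.03,Prob:0.03):0.0225):0.015):0.01725):0.02025,(Hgla:0.0615,Cpor:0.0615):0.0435);
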