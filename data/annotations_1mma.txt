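# secondary-structure cluster labels for the excited residues
# of the published case study (chain A author numbering)
A:90 loop_Nterm_lever
A:91 loop_Nterm_lever
A:105 helix5
A:109 helix5
A:110 helix5
A:115 beta1
A:116 beta1
A:117 beta1
A:118 beta1
A:119 beta1
A:121 beta2
A:122 beta2
A:123 beta2
A:124 beta2
A:125 beta2
A:126 beta2
A:127 beta2
A:128 beta2
A:129 beta2
A:130 beta2
A:131 beta2
A:174 beta4_Ploop
A:175 beta4_Ploop
A:176 beta4_Ploop
A:178 beta4_Ploop
A:179 beta4_Ploop
A:180 beta4_Ploop
A:181 beta4_Ploop
A:182 beta4_Ploop
A:183 beta4_Ploop
A:184 beta4_Ploop
A:185 beta4_Ploop
A:188 helix9
A:189 helix9
A:193 helix9
A:233 beta6_switch1
A:236 beta6_switch1
A:454 beta5_switch2
A:455 beta5_switch2
A:456 beta5_switch2
A:457 beta5_switch2
A:651 beta3
A:652 beta3
A:653 beta3
A:655 beta3
A:656 beta3
A:657 beta3
A:658 beta3
A:659 beta3
A:663 loop_SH1
A:664 loop_SH1
A:665 loop_SH1
A:666 loop_SH1
A:671 SH1_helix
A:672 SH1_helix
A:675 SH1_helix
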