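# secondary-structure cluster labels for the excited residues
# of the published case study (chain A author numbering)
A:325 betaB
A:328 betaB
A:329 betaB
A:330 betaB
A:331 betaB
A:333 betaC
A:334 betaC
A:335 betaC
A:336 betaC
A:339 betaC
A:341 betaC
A:342 betaC
A:358 betaD
A:359 betaD
A:360 betaD
A:361 betaD
A:366 betaE_loop
A:367 betaE_loop
A:368 betaE_loop
A:369 betaE_loop
A:370 alpha2_loop
A:371 alpha2_loop
A:372 alpha2_loop
A:373 alpha2_loop
A:374 alpha2_loop
A:375 alpha2_loop
A:376 alpha2_loop
A:377 alpha2_loop
A:378 alpha2_loop
A:380 alpha2_loop
A:381 alpha2_loop
A:383 alpha2_loop
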