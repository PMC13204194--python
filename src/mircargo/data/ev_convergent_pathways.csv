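pathway,p_mirna_targets,p_rnaseq
PIP3 activates AKT signalling,1.93e-7,8.61e-6
Signalling by WNT,1.40e-15,1.36e-4
Transcriptional activity of SMAD2/SMAD3:SMAD4 heterotrimer,1.06e-7,1.43e-4
Regulation of mitotic cell cycle,3.02e-12,2.10e-4
TCF-dependent signalling in response to WNT,1.06e-10,3.74e-4
Deactivation of the beta-catenin transactivating complex,7.37e-8,9.87e-4
Beta-catenin-independent WNT signalling,9.08e-8,1.50e-3
Signalling by ERBB2,3.52e-10,2.18e-3
Signalling by FGFR2,2.08e-9,2.22e-3
SMAD2/SMAD3:SMAD4 heterotrimer regulates transcription,2.88e-6,2.68e-3
Oncogene Induced Senescence,5.16e-10,3.01e-3
G2/M Checkpoints,1.51e-10,3.89e-3
Downstream signalling events of B Cell Receptor (BCR),6.81e-9,4.22e-3
Signalling by FGFR,2.08e-9,5.32e-3
Programmed Cell Death,2.55e-12,5.50e-3
Signalling by FGFR3,2.08e-9,6.08e-3
Apoptosis,2.47e-12,6.09e-3
Signalling by FGFR4,2.08e-9,6.65e-3
Cell Cycle Checkpoints,1.54e-9,8.25e-3
Signalling by EGFR in Cancer,5.94e-12,1.05e-2
Fc epsilon receptor (FCERI) signalling,1.92e-15,1.19e-2
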