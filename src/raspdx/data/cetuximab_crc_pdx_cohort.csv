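model_id,ras_score,delta_t_over_delta_c,kras_allele
CR0047,0.105,0.27,G12C
CR0150,-0.149,0.43,G12D
CR0455,0.228,0.86,G12D
CR1554,0.113,0.69,G12V
CR0231,-0.129,-0.13,G13D
CR2520,0.223,0.01,G13D
CR0588,-0.315,0.11,G13D
CR0193,-0.214,0.16,G13D
CR2226,0.605,0.62,G13D
CR0012,0.472,0.81,G13D
CR2110,-0.424,-0.48,WT
CR2502,-0.684,-0.09,WT
CR0170,-0.746,-0.07,WT
CR0196,0.096,-0.06,WT
CR0560,-0.372,0.28,WT
CR0205,-0.396,0.34,WT
CR1530,0.038,0.52,WT
CR1519,-0.102,0.67,WT
CR0245,-0.081,0.69,WT
CR0004,0.375,0.75,WT
CR1574,0.025,0.88,WT
CR0029,0.326,0.95,WT
CR0146,0.578,1.18,WT
CR1744,-0.064,1.29,WT
CR0010,0.145,1.58,WT
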