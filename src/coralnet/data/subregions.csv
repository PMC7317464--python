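subregion,region,t_mmm_2005_c
Great Barrier Reef,Pacific Ocean,28.68
Central Pacific,Pacific Ocean,27.60
Japan,Pacific Ocean,28.54
Eastern Pacific,Pacific Ocean,27.63
Western Pacific,Pacific Ocean,29.56
American Samoa,Pacific Ocean,29.87
Phuket,Indian Ocean,30.38
Western Indian,Indian Ocean,28.97
Western Australia,Indian Ocean,28.78
Western Caribbean,Caribbean Sea,29.72
Eastern Caribbean,Caribbean Sea,29.63
Central Caribbean,Caribbean Sea,29.94
Florida,Caribbean Sea,30.25
Gulf of Mexico,Caribbean Sea,30.54
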