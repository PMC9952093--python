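aeruginosa	Pseudomonas
aureus	Staphylococcus
burgdorferi	Borrelia
cereus	Bacillus
cloacae	Enterobacter
coli	Escherichia
epidermidis	Staphylococcus
faecalis	Enterococcus
gingivalis	Porphyromonas
hirea	Enterococcus
intermedia	Prevotella
micra	Parvimonas
mirabilis	Proteus
monocytogenes	Listeria
montevideo	Salmonella
mutans	Streptococcus
nucleatum	Fusobacterium
oralis	Streptococcus
pneumoniae	Klebsiella
pylori	Helicobacter
saprophiticus	Staphylococcus
sobrinus	Streptococcus
subtilis	Bacillus
typhimurium	Salmonella
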