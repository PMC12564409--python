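# Estimated divergence times (million years) between Homo sapiens and 40
# mammalian species, as compiled from the TimeTree database (timetree.org).
# The human row (delta_t_my = 0) anchors the table.
scientific_name	common_name	delta_t_my	order
Homo sapiens	Human	0	Primates
Balaenoptera acutorostrata	Minke whale	94	Cetartiodactyla
Bison bison	American bison	94	Cetartiodactyla
Callithrix jacchus	Common marmoset	42	Primates
Canis lupus	Gray wolf	94	Carnivora
Carlito syrichta	Philippine tarsier	68	Primates
Cavia porcellus	Guinea pig	87	Rodentia
Chlorocebus sabaeus	Green monkey	28	Primates
Cricetulus griseus	Chinese hamster	87	Rodentia
Dasypus novemcinctus	Nine-banded armadillo	99	Cingulata
Dipodomys ordii	Ord's kangaroo rat	87	Rodentia
Equus caballus	Horse	94	Perissodactyla
Erinaceus europaeus	European hedgehog	94	Eulipotyphla
Felis catus	Cat	94	Carnivora
Galeopterus variegatus	Sunda flying lemur	79	Dermoptera
Gorilla gorilla	Gorilla	8	Primates
Loxodonta africana	African elephant	99	Proboscidea
Macaca fascicularis	Crab-eating macaque	28	Primates
Macaca mulatta	Rhesus macaque	28	Primates
Monodelphis domestica	Gray short-tailed opossum	160	Didelphimorphia
Mus musculus	House mouse	87	Rodentia
Mustela putorius	Ferret	94	Carnivora
Myotis lucifugus	Little brown bat	94	Chiroptera
Nasalis larvatus	Proboscis monkey	28	Primates
Neomonachus schauinslandi	Hawaiian monk seal	94	Carnivora
Nomascus leucogenys	Northern white-cheeked gibbon	19	Primates
Ochotona princeps	American pika	87	Lagomorpha
Ornithorhynchus anatinus	Platypus	180	Monotremata
Otolemur garnettii	Small-eared galago	73	Primates
Ovis orientalis	Mouflon	94	Cetartiodactyla
Pan paniscus	Bonobo	6	Primates
Pan troglodytes	Chimpanzee	6	Primates
Papio anubis	Olive baboon	28	Primates
Pongo abelii	Sumatran orangutan	15	Primates
Procavia capensis	Rock hyrax	99	Hyracoidea
Rattus norvegicus	Norway rat	87	Rodentia
Sarcophilus harrisii	Tasmanian devil	160	Dasyuromorphia
Sorex araneus	Common shrew	94	Eulipotyphla
Sus scrofa	Pig	94	Cetartiodactyla
Tupaia glis	Tree shrew	84	Scandentia
Tursiops truncatus	Bottlenose dolphin	94	Cetartiodactyla
Vicugna pacos	Alpaca	94	Cetartiodactyla
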