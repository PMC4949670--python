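# One genus per line. Genera listed here are flagged as extant: their
# extinction time is pinned at the present (0 Ma) during inference.
# This packaged list is a starting point and is meant to be edited or
# replaced by a user-supplied list covering the dataset at hand.
Acer
Alnus
Araucaria
Betula
Carya
Cedrus
Cinnamomum
Cupressus
Cycas
Dicksonia
Ephedra
Equisetum
Fagus
Ficus
Ginkgo
Gleichenia
Ilex
Isoetes
Juglans
Juniperus
Larix
Laurus
Liquidambar
Liriodendron
Lycopodium
Magnolia
Marattia
Myrica
Nelumbo
Nymphaea
Osmunda
Picea
Pinus
Platanus
Podocarpus
Populus
Quercus
Salix
Salvinia
Sassafras
Selaginella
Sequoia
Taxodium
Taxus
Typha
Ulmus
Vitis
Zamia
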