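# Supra-generic taxon -> vegetation group used in the group-level analyses.
# Keys are matched case-insensitively against the taxonomy columns of each
# occurrence (phylum, class, order, family as provided by the source table).
# Values: spore_bearing | nonflowering_seed | angiosperm | other
# Users should extend this table to cover the labels present in their download.

# --- spore-bearing vascular plants (early tracheophytes, lycophytes,
#     sphenophytes, ferns and allies, progymnosperms) ---
Rhyniopsida: spore_bearing
Zosterophyllopsida: spore_bearing
Trimerophytopsida: spore_bearing
Horneophytopsida: spore_bearing
Lycopodiopsida: spore_bearing
Lycopsida: spore_bearing
Isoetopsida: spore_bearing
Lycopodiales: spore_bearing
Lepidodendrales: spore_bearing
Isoetales: spore_bearing
Selaginellales: spore_bearing
Sphenophyllales: spore_bearing
Equisetopsida: spore_bearing
Sphenopsida: spore_bearing
Equisetales: spore_bearing
Calamitales: spore_bearing
Polypodiopsida: spore_bearing
Filicopsida: spore_bearing
Pteridopsida: spore_bearing
Marattiales: spore_bearing
Osmundales: spore_bearing
Filicales: spore_bearing
Polypodiales: spore_bearing
Gleicheniales: spore_bearing
Schizaeales: spore_bearing
Salviniales: spore_bearing
Marsileales: spore_bearing
Cladoxylopsida: spore_bearing
Progymnospermopsida: spore_bearing
Archaeopteridales: spore_bearing
Aneurophytales: spore_bearing
Psilophytopsida: spore_bearing
Psilophytales: spore_bearing

# --- nonflowering seed plants ('gymnosperms' in the broad sense,
#     including seed ferns and bennettitaleans) ---
Pinopsida: nonflowering_seed
Pinidae: nonflowering_seed
Pinales: nonflowering_seed
Coniferales: nonflowering_seed
Voltziales: nonflowering_seed
Cordaitales: nonflowering_seed
Cordaitopsida: nonflowering_seed
Cycadopsida: nonflowering_seed
Cycadidae: nonflowering_seed
Cycadales: nonflowering_seed
Ginkgoopsida: nonflowering_seed
Ginkgoidae: nonflowering_seed
Ginkgoales: nonflowering_seed
Gnetopsida: nonflowering_seed
Gnetidae: nonflowering_seed
Gnetales: nonflowering_seed
Bennettitales: nonflowering_seed
Cycadeoideales: nonflowering_seed
Pteridospermopsida: nonflowering_seed
Pteridospermales: nonflowering_seed
Peltaspermales: nonflowering_seed
Caytoniales: nonflowering_seed
Corystospermales: nonflowering_seed
Glossopteridales: nonflowering_seed
Medullosales: nonflowering_seed
Lyginopteridales: nonflowering_seed
Czekanowskiales: nonflowering_seed

# --- flowering seed plants ---
Angiospermae: angiosperm
Magnoliopsida: angiosperm
Liliopsida: angiosperm
Magnoliidae: angiosperm
Rosidae: angiosperm
Asteridae: angiosperm
Hamamelididae: angiosperm
Dilleniidae: angiosperm
Caryophyllidae: angiosperm
Alismatidae: angiosperm
Arecidae: angiosperm
Commelinidae: angiosperm
Zingiberidae: angiosperm
Liliidae: angiosperm
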