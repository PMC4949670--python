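# Column-map "dialect" for reading occurrence downloads.  Each logical field
# lists the table column names tried in order; the first one present wins.
# Edit or replace this file if your download uses different headers.
occurrence_id: [occurrence_no, occurrence.occurrence_no, record_id]
taxon_name: [accepted_name, taxon_name, identified_name, occurrence.species_name]
rank: [accepted_rank, taxon_rank, identified_rank]
min_age: [min_ma, ma_min, minimum_age]
max_age: [max_ma, ma_max, maximum_age]
organ: [plant_organ, preservation, plant_organ2, preservation_quality]
taxonomy: [phylum, class, order, family]

# Keyword table mapping the organ / preservation column to an organ class.
# Any record whose organ field contains one of these substrings
# (case-insensitive) gets the corresponding class; records matching a
# microfossil keyword are classed microfossil even if they also match a
# macrofossil keyword; records with an empty organ field are "unknown".
organ_keywords:
  microfossil: [pollen, spore, cryptospore, palynomorph, acritarch, dinoflagellate]
  macrofossil: [leaf, leaves, frond, stem, axis, wood, trunk, root, seed, fruit,
                flower, cone, strobilus, sporangi, whole, compression, impression,
                cast, petrifaction, permineral, charcoal, cuticle, megaspore]
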