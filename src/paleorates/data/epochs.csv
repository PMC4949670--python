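label,older_bound_Ma,younger_bound_Ma
Terreneuvian,541.0,521.0
Cambrian Series 2,521.0,509.0
Cambrian Series 3,509.0,497.0
Furongian,497.0,485.4
Early Ordovician,485.4,470.0
Middle Ordovician,470.0,458.4
Late Ordovician,458.4,443.8
Llandovery,443.8,433.4
Wenlock,433.4,427.4
Ludlow,427.4,423.0
Pridoli,423.0,419.2
Early Devonian,419.2,393.3
Middle Devonian,393.3,382.7
Late Devonian,382.7,358.9
Mississippian,358.9,323.2
Pennsylvanian,323.2,298.9
Cisuralian,298.9,272.3
Guadalupian,272.3,259.8
Lopingian,259.8,252.2
Early Triassic,252.2,247.2
Middle Triassic,247.2,237.0
Late Triassic,237.0,201.3
Early Jurassic,201.3,174.1
Middle Jurassic,174.1,163.5
Late Jurassic,163.5,145.0
Early Cretaceous,145.0,100.5
Late Cretaceous,100.5,66.0
Paleocene,66.0,56.0
Eocene,56.0,33.9
Oligocene,33.9,23.0
Miocene,23.0,5.3
Pliocene,5.3,2.6
Quaternary,2.6,0.0
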