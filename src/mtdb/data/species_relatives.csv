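species,related_species
Chelonia mydas,Caretta caretta
Caretta caretta,Chelonia mydas
Dermochelys coriacea,Chelonia mydas
Dermochelys coriacea,Caretta caretta
Malaclemys terrapin,Chelydra serpentina
Chelydra serpentina,Malaclemys terrapin
Nerodia sipedon,Nerodia rhombifera
Nerodia rhombifera,Nerodia sipedon
Enhydris chinensis,Nerodia sipedon
Alligator mississippiensis,Crocodylus porosus
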