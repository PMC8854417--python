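species_id,regime,substrategy
Amobia signata,SAT,satellite
Apodacra seriemaculata,SAT,satellite
Craticulina tabaniformis,SAT,satellite
Eumacronychia persolla,NON_SAT,
Metopia argyrocephala,NON_SAT,hole_searcher
Miltogramma germari,SAT,satellite
Miltogramma punctata,SAT,satellite
Miltogramma turanica,SAT,satellite
Phrosinella fedtshenkoi,NON_SAT,hole_searcher
Phrosinella kocaki,NON_SAT,hole_searcher
Phylloteles pictipennis,NON_SAT,necrophagous
Pterella melanura,SAT,satellite
Senotainia albifrons,SAT,satellite
Senotainia conica,SAT,satellite
Senotainia tricuspis,SAT,satellite
Sphenometopa claripennis,NON_SAT,
Taxigramma heteroneura,NON_SAT,stalker_lurker
Taxigramma stictica,NON_SAT,stalker_lurker
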