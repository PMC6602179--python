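# Region adjacency for the 13 administrative regions of Burkina Faso.
# One undirected edge per line: "regionA<TAB>regionB".
# Transcribed from the administrative map; approximate where borders are short.
Boucle du Mouhoun	Nord
Boucle du Mouhoun	Hauts Bassins
Boucle du Mouhoun	Centre-Ouest
Cascades	Hauts Bassins
Cascades	Sud-Ouest
Hauts Bassins	Sud-Ouest
Sud-Ouest	Centre-Ouest
Centre-Ouest	Centre
Centre-Ouest	Centre-Sud
Centre	Plateau Central
Centre	Centre-Sud
Centre-Sud	Centre-Est
Centre-Est	Plateau Central
Centre-Est	Est
Plateau Central	Centre-Nord
Centre-Nord	Nord
Centre-Nord	Sahel
Centre-Nord	Est
Nord	Sahel
Sahel	Est
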