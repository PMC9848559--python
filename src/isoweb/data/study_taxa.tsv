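taxon	group	res1	res2	res3	res4	res5	res6	res7	res8	res9	res10	res11	res12
benthic algae	basal	1	0	1	1	1	0	1	0	1	1	1	1
emergent macrophytes	basal	0	0	0	0	0	0	0	0	0	0	0	1
floating macrophytes	basal	0	1	0	0	0	0	0	0	0	0	0	0
macrophytes	basal	0	0	0	0	0	0	0	1	1	1	1	1
periphyton	basal	0	0	0	0	0	1	1	1	1	1	1	1
phytoplankton	basal	1	1	1	1	1	1	0	1	0	1	1	1
riparian grasses	basal	1	1	1	1	0	1	1	1	0	0	1	1
riparian plants	basal	1	1	1	1	1	1	1	1	1	1	1	1
unknown producer	basal	0	0	0	0	0	0	1	1	1	0	0	0
Ampullariidae	invertebrate	1	0	1	1	0	0	1	0	0	1	1	1
Bivalvia	invertebrate	0	0	0	0	0	0	1	1	0	0	0	1
Conchostraca	invertebrate	0	0	0	0	0	0	0	1	1	1	0	1
Decapoda	invertebrate	1	1	1	1	1	1	1	1	1	1	1	1
Chironomidae	invertebrate	1	1	1	1	1	1	1	1	1	1	1	1
Ephemeroptera	invertebrate	1	0	0	0	0	0	0	1	0	1	1	1
Gastropoda	invertebrate	1	1	1	1	1	1	1	1	1	1	1	1
Hemiptera	invertebrate	0	0	0	0	0	0	0	1	1	1	1	1
Hirudinea	invertebrate	0	1	0	0	0	0	0	0	0	0	0	0
Nassariidae	invertebrate	0	0	0	0	0	0	1	0	0	0	0	1
Odonata	invertebrate	1	0	1	1	1	1	1	1	1	1	1	1
Oligochaeta	invertebrate	0	0	0	0	0	0	1	0	0	0	0	1
Ostracoda	invertebrate	1	0	1	1	0	0	0	0	0	0	0	1
Trichoptera	invertebrate	0	0	0	0	0	1	0	0	1	0	0	0
Copepoda	invertebrate	1	1	1	1	1	1	1	1	1	1	1	1
Acarichthys heckelii	fish	0	1	0	0	0	0	0	1	1	1	1	1
Amphilophus citrinellus	fish	0	1	1	0	1	0	1	0	0	0	0	0
Aplocheilus armatus	fish	0	0	0	0	0	0	0	0	1	0	0	0
Atractosteus spatula	fish	0	0	0	0	0	0	0	0	0	0	0	0
Barbonymus schwanefeldii	fish	0	1	0	0	0	0	1	0	0	0	0	0
Channa lucius	fish	0	0	0	0	0	0	0	0	0	1	0	0
Channa micropeltes	fish	0	0	0	1	0	1	1	1	1	1	1	1
Channa striata	fish	0	1	1	1	1	1	1	1	1	1	1	1
Chitala ornata	fish	0	0	0	1	0	1	0	0	1	0	1	1
Cichla orinocensis	fish	1	1	1	1	1	0	0	1	1	0	0	0
Cichla spp.	fish	0	0	0	0	0	0	1	0	0	1	1	1
Cichla temensis	fish	1	1	0	0	0	1	0	1	1	0	0	0
Clarias gariepinus	fish	1	0	1	0	0	0	0	0	0	0	0	0
Cyclocheilichthys apogon	fish	0	0	0	0	0	0	0	0	1	0	0	0
Cyprinus carpio	fish	0	0	0	0	0	0	0	0	0	0	0	0
Datnioides microlepis	fish	1	0	0	0	0	0	0	0	0	0	0	0
Dermogenys collettei	fish	0	0	0	0	0	0	1	0	0	0	0	1
Etroplus suratensis	fish	1	1	0	1	1	0	1	0	0	0	1	1
Gambusia affinis	fish	0	0	0	0	0	0	1	0	0	1	0	0
Geophagus altifrons	fish	1	1	0	0	1	1	1	1	1	1	1	1
Glossogobius aureus	fish	1	1	0	1	1	1	0	1	1	0	1	1
Gobiidae	fish	0	0	0	0	0	0	0	0	0	1	0	1
Hemigrammus rodwayi	fish	0	0	0	0	0	0	0	0	0	0	0	1
Heterotilapia buttikoferi	fish	1	1	1	0	1	1	1	0	0	1	0	0
Hyporhamphus quoyi	fish	0	0	0	1	0	0	0	0	0	0	0	0
Leptobarbus rubripinna	fish	0	0	0	0	0	0	1	0	0	0	0	0
Macrognathus zebrinus	fish	0	0	0	0	0	0	0	0	0	0	1	0
Mayaheros urophthalmus	fish	0	1	0	1	0	0	1	0	0	0	0	0
Megalops cyprinoides	fish	1	0	0	0	0	0	0	0	0	0	0	0
Monopterus javanensis	fish	0	0	1	1	0	1	0	1	1	0	0	0
Notopterus notopterus	fish	0	0	1	0	0	0	0	0	0	1	1	1
Oreochromis mossambicus	fish	0	1	0	0	1	0	0	0	0	0	0	0
Oreochromis niloticus	fish	0	1	0	1	1	0	1	0	0	0	0	1
Oreochromis spp. (hybrid)	fish	1	0	0	0	1	0	0	0	0	0	0	0
Oryzias javanicus	fish	0	0	0	0	1	0	0	0	0	0	0	0
Osphronemus goramy	fish	0	0	0	0	1	1	1	1	0	1	1	1
Osteochilus vittatus	fish	0	0	0	0	0	0	0	0	1	0	0	0
Oxyeleotris marmorata	fish	1	1	1	1	1	1	1	1	1	1	1	1
Parachromis managuense	fish	0	0	1	0	0	0	0	0	0	0	0	0
Parambassis siamensis	fish	0	0	1	0	0	0	1	0	1	0	0	1
Potamotrygon motoro	fish	0	0	0	0	0	0	0	1	0	1	1	0
Pterygoplichthys disjunctivus	fish	0	1	0	0	1	0	0	0	0	0	0	0
Pterygoplichthys pardalis	fish	0	1	0	0	0	0	0	0	0	0	0	1
Pterygoplichthys spp.	fish	0	0	0	0	0	0	1	0	0	0	0	0
Rasbora boraptensis	fish	0	0	0	0	0	0	0	0	0	0	1	0
Rhinogobius similis	fish	1	0	1	1	1	0	0	0	0	0	0	0
Scleropages formosus	fish	0	0	0	0	0	1	0	1	1	1	0	0
Vieja melanura	fish	0	1	1	0	1	0	1	0	0	0	0	0
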