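# Synthetic fixture peptide-marker reference database.
# Species, compound ZooMS taxa, families, orders and marker letters follow
# standard ZooMS usage; the masses are synthetic test stand-ins, NOT curated
# biological marker values. Schema: species,zooms_taxon,family,order,marker_id,mass,region
species,zooms_taxon,family,order,marker_id,mass,region
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,A,1105.6,Africa
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,B,1453.7,Africa
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,C,1579.8,Africa
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,D,2115.1,Africa
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,E,2808.4,Africa
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,F,2853.4,Africa
Loxodonta africana,Loxodonta sp.,Elephantidae,Proboscidea,G,3100.4,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,A,1105.6,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,B,1427.7,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,C,1580.8,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,D,2131.1,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,E,2792.4,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,F,2869.5,Africa
Giraffa camelopardalis,Giraffa sp.,Giraffidae,Artiodactyla,G,3033.6,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,A,1105.6,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,B,1427.7,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,C,1580.8,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,D,2131.1,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,E,2792.4,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,F,2853.4,Africa
Syncerus caffer,Syncerus sp.,Bovidae,Artiodactyla,G,3093.5,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,A,1093.5,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,B,1439.7,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,C,1566.8,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,D,2129.1,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,E,2780.4,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,F,2841.4,Africa
Orycteropus afer,Orycteropus sp.,Orycteropodidae,Tubulidentata,G,3017.4,Africa
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,A,1105.6,Eurasia
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,B,1427.7,Eurasia
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,C,1580.8,Eurasia
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,D,2131.1,Eurasia
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,E,2883.4,Eurasia
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,F,3017.4,Eurasia
Ovis aries,Ovis sp.,Bovidae,Artiodactyla,G,3093.5,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,A,1105.6,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,B,1427.7,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,C,1580.8,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,D,2131.1,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,E,2792.4,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,F,3017.4,Eurasia
Bos primigenius,Bos/Bison,Bovidae,Artiodactyla,G,3033.5,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,A,1105.6,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,B,1427.7,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,C,1580.8,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,D,2145.1,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,E,2792.4,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,F,2883.4,Eurasia
Cervus elaphus,Cervus/Saiga/Gazella,Cervidae,Artiodactyla,G,3033.5,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,A,1105.6,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,B,1427.7,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,C,1530.7,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,D,2115.1,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,E,2792.4,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,F,2853.4,Eurasia
Equus caballus,Equus sp.,Equidae,Perissodactyla,G,3093.5,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,A,1105.6,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,B,1453.7,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,C,1566.8,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,D,2131.1,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,E,2808.4,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,F,2869.5,Eurasia
Ursus arctos,Ursus sp.,Ursidae,Carnivora,G,3017.4,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,A,1105.6,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,B,1453.7,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,C,1566.8,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,D,2129.1,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,E,2820.4,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,F,2853.4,Eurasia
Mustela putorius,Mustela sp.,Mustelidae,Carnivora,G,3033.5,Eurasia
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,A,1105.6,NewWorld
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,B,1453.7,NewWorld
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,C,1580.8,NewWorld
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,D,2129.1,NewWorld
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,E,2792.4,NewWorld
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,F,2853.4,NewWorld
Tapirus terrestris,Tapirus sp.,Tapiridae,Perissodactyla,G,3033.5,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,A,1105.6,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,B,1427.7,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,C,1580.8,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,D,2145.1,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,E,2792.4,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,F,2869.5,NewWorld
Lama glama,Lama sp.,Camelidae,Artiodactyla,G,3017.4,NewWorld
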