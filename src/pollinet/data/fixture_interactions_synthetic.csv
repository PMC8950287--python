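day,plant,pollinator,visits
149,Polygonatum odoratum var. pluriflorum,Lasioglossum exiliceps,1
149,Polygonatum odoratum var. pluriflorum,Lasioglossum virideglaucum,1
149,Ranunculus japonicus,Andrena sp. 1,1
149,Ranunculus japonicus,Apis mellifera,1
149,Ranunculus japonicus,Bombylius major,1
149,Ranunculus japonicus,Curculionidae sp. 1,1
149,Ranunculus japonicus,Lasioglossum duplex,1
149,Ranunculus japonicus,Lasioglossum virideglaucum,1
149,Ranunculus japonicus,Lasioglossum miyabei,1
149,Ranunculus japonicus,Metasyrphus luniger,1
149,Ranunculus japonicus,Oedemeridae sp. 1,1
149,Ranunculus japonicus,Parnassius stubbendorfii,1
149,Rhododendron schlippenbachii,Andrena sp. 1,1
149,Rhododendron schlippenbachii,Elateridae sp. 1,1
149,Rhododendron schlippenbachii,Eucera sp. 1,1
149,Rhododendron schlippenbachii,Lasioglossum virideglaucum,1
149,Rhododendron schlippenbachii,Metasyrphus luniger,1
149,Cypripedium guttatum,Oedemeridae sp. 1,1
149,Aruncus dioicus var. kamtschaticus,Lasioglossum virideglaucum,1
149,Aruncus dioicus var. kamtschaticus,Pristomyrmex pungens,1
149,Weigela florida,Apis mellifera,1
149,Weigela florida,Bombylius major,1
149,Weigela florida,Eristalomyia tenax,1
149,Weigela florida,Lasioglossum virideglaucum,1
149,Arabis gemmifera,Carterocephalus silvicola,1
149,Arabis gemmifera,Lasioglossum virideglaucum,1
149,Arabis gemmifera,Metasyrphus luniger,1
149,Arabis gemmifera,Philopota nigroaenea,1
149,Arabis gemmifera,Vespidae sp. 1,1
149,Taraxacum officinale,Metasyrphus luniger,1
149,Barbarea vulgaris,Lasioglossum duplex,1
149,Valeriana fauriei,Apis mellifera,1
149,Valeriana fauriei,Lasioglossum exiliceps,1
149,Valeriana fauriei,Lasioglossum duplex,1
149,Valeriana fauriei,Lasioglossum virideglaucum,1
149,Valeriana fauriei,Lasioglossum miyabei,1
149,Valeriana fauriei,Metasyrphus luniger,1
149,Valeriana fauriei,Oedemeridae sp. 1,1
149,Cerastium holosteoides var. hallaisanensis,Ceratina flavipes,1
149,Cerastium holosteoides var. hallaisanensis,Curculionidae sp. 1,1
149,Cerastium holosteoides var. hallaisanensis,Lasioglossum virideglaucum,1
149,Cerastium holosteoides var. hallaisanensis,Parnassius stubbendorfii,1
149,Viola mandshurica,Lasioglossum virideglaucum,0
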