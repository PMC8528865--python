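name	parent	union_members	provisional
InformationContentEntity
TextualEntity	InformationContentEntity
AnnotationInText	InformationContentEntity
NamedEntity	TextualEntity
NamedEntityGroup	TextualEntity
Relationship	TextualEntity
Pronoun	TextualEntity
AnatomicalPart	NamedEntity
BodyPart	AnatomicalPart
CellularComponent	AnatomicalPart
Cell	AnatomicalPart
Chemical	NamedEntity
Protein	Chemical
NucleicAcid	Chemical
Gene	NucleicAcid
Drug	Chemical
AminoAcid	Chemical
Peptide	Chemical
GeneOrProtein	Chemical	Gene|Protein
AminoAcidOrPeptide	Chemical	AminoAcid|Peptide
Process	NamedEntity
BiologicalProcess	Process
MolecularProcess	Process
MedicalProcedure	Process
ResearchActivity	Process
MentalProcess	Process
NaturalProcess	Process		yes
MedicalDevice	NamedEntity
MedicalProcedureOrDevice	NamedEntity	MedicalProcedure|MedicalDevice
MedicalFinding	NamedEntity
ExperimentalFactor	NamedEntity		yes
GeographicalLocation	NamedEntity		yes
Duration	NamedEntity
IntellectualProduct	NamedEntity
Measurement	NamedEntity
Quantity	NamedEntity
QuantityOrMeasurement	NamedEntity	Quantity|Measurement
Organism	NamedEntity
PersonGroup	NamedEntity
PublishedSourceOfInformation	NamedEntity
Publication	PublishedSourceOfInformation
Journal	PublishedSourceOfInformation
Citation	PublishedSourceOfInformation
PublicationOrCitation	PublishedSourceOfInformation	Publication|Citation
Unit	NamedEntity
Language	NamedEntity
Facility	NamedEntity
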