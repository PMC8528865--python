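label	surfaces
GeneOrProtein	hemoglobin-a2|kinase-p71|zorbin|tp53x|relA-factor|crm9
Gene	genZ1|locus-vx|orf221|genQ7
Protein	protamexin|catalase-B|lysozyme-K|p88core
NucleicAcid	rna-vk2|dsDNA-m3|oligo-t44
Drug	veldexamab|cortizane|riluzene|simvastol
AminoAcid	glycinate|leucinol|valexine
Peptide	peptor-9|braxipep|melanotide
Chemical	sulfonex|nitrozol|ferricate
AminoAcidOrPeptide	argipex|tyrosal
Process	flux-cycling|bioconversion|catabolation
BiologicalProcess	apoptogenesis|myelinolysis|angiosprouting
MolecularProcess	transphosphation|ubiquityl-cycling
MedicalProcedure	angioscopy|lobexectomy|cryoplasty
ResearchActivity	microtitration|cohort-screen
MentalProcess	recall-tasking|anhedonia-drift
MedicalDevice	stentoflex|cannulex|pacerod
MedicalProcedureOrDevice	shuntography|lithoclave
MedicalFinding	hyperplexia|ferropenia|nodulosis
BodyPart	hepatic-lobule|metacarpus|vermis
CellularComponent	nucleolus-band|vacuosome
Cell	astroglyte|myeloblast-k|chondrocyne
Organism	m-tuberculans|c-elegaris|h-sapiex
Measurement	titer-index|lumens-ratio
Quantity	picomolarity|dose-fraction
QuantityOrMeasurement	assay-magnitude|unit-burden
Duration	fortnight-course|decade-lag
IntellectualProduct	atlas-schema|codex-panel
PublishedSourceOfInformation	preprint-ledger|monograph-x
Publication	trialreport-52|casebook-d
Journal	j-neurozym|acta-fictiva
Citation	ref-kappa|ibid-9
PublicationOrCitation	corpus-note|errata-5
PersonGroup	probandry|cohort-nine
GeographicalLocation	eastmoor-basin|kaluga-delta
ExperimentalFactor	photoperiod-x|diet-arm
Facility	biovault-lab|isolation-ward
Unit	millikat|decigray
Language	latinate|hellenic
NaturalProcess	erosion-flux|thermal-drift
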