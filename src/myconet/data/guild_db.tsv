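# Curated guild lookup table (synthetic test fixture, hand-written for this
# package; NOT an export of the FUNGuild database). Columns follow the
# FUNGuild TSV convention.
taxon	taxonomicLevel	trophicMode	guild	confidenceRanking
Glomeromycota	phylum	Symbiotroph	Arbuscular Mycorrhizal	Probable
Glomus	genus	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable
Rhizophagus	genus	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable
Funneliformis	genus	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable
Tuber	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Russula	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Inocybe	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Mortierella	genus	Saprotroph	Undefined Saprotroph	Highly Probable
Mortierellomycota	phylum	Saprotroph	Undefined Saprotroph	Possible
Chaetomium	genus	Saprotroph	Undefined Saprotroph	Probable
Penicillium	genus	Saprotroph	Undefined Saprotroph	Probable
Agaricus	genus	Saprotroph	Undefined Saprotroph	Probable
Fusarium	genus	Pathotroph-Saprotroph	Plant Pathogen|Undefined Saprotroph	Probable
Alternaria	genus	Pathotroph-Saprotroph	Plant Pathogen|Undefined Saprotroph	Probable
Gibberella	genus	Pathotroph	Plant Pathogen	Highly Probable
Ustilago	genus	Pathotroph	Plant Pathogen	Highly Probable
Metarhizium	genus	Pathotroph	Animal Pathogen	Highly Probable
Beauveria	genus	Pathotroph	Animal Pathogen	Highly Probable
Cladosporium	genus	Pathotroph-Saprotroph-Symbiotroph	Endophyte|Plant Pathogen|Undefined Saprotroph	Possible
Chytridiomycota	phylum	Pathotroph-Saprotroph	Plant Pathogen|Undefined Saprotroph	Possible
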