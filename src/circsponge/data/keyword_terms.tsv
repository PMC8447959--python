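# Vascular-endothelial keyword terms: which GO/pathway ids carry which
# function flags. Editable data, not code; comma-separate multiple functions.
term_id	source	functions
GO:0001525	GO	angiogenesis
GO:0045765	GO	angiogenesis
GO:0045766	GO	angiogenesis
GO:0010573	GO	angiogenesis
GO:0010574	GO	angiogenesis
GO:0002040	GO	angiogenesis
GO:0001935	GO	proliferation
GO:0001938	GO	proliferation
GO:0043542	GO	migration
GO:0043536	GO	migration
mmu04512	pathway	proliferation,migration
mmu04014	pathway	proliferation,migration,angiogenesis
mmu04151	pathway	proliferation,migration,angiogenesis
mmu04370	pathway	proliferation,migration,angiogenesis
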