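# Vitamin C equivalent antioxidant capacity (VCE) coefficients, mg VCE per mg compound.
# PLACEHOLDER VALUES: every coefficient below is 1.0, i.e. TAC degenerates to total
# antioxidant mass intake. Replace with ABTS-assay VCE values from the literature
# before any substantive analysis; vitamin C is 1.0 by definition of the unit.
compound,vce_mg_per_mg,provenance
vitamin_c,1.0,definition of VCE unit
vitamin_e,1.0,placeholder - supply literature value
carotenoids,1.0,placeholder - supply literature value
flavonoids,1.0,placeholder - supply literature value
isoflavones,1.0,placeholder - supply literature value
proanthocyanidins,1.0,placeholder - supply literature value
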