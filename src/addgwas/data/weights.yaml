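# Gene-prioritization evidence weights.
#
# Exemplar weight table satisfying the scheme's ordering constraints:
# replicated evidence (the same gene/domain/subcategory observed in two or
# more datasets) outweighs a single hit, and brain-derived evidence (bulk
# brain, microglia, DLPFC) outweighs peripheral evidence (LCLs,
# monocytes/macrophages, blood).  Sites with access to a calibrated weight
# table can transcribe it here without code changes.
#
# Lookup key: weights[domain][subcategory][tissue_class][single|replicated],
# where tissue_class is "brain", "peripheral" or "na" (the category column of
# an evidence item is mapped to a class via brain_categories /
# peripheral_categories below).

max_score: 25.0

brain_categories: [brain_bulk, microglia, dlpfc]
peripheral_categories: [lcl, monocyte_macrophage, blood]

weights:
  variant_annotation:
    nearest_gene:
      na: {single: 2.0, replicated: 2.0}
    rare_variant:
      na: {single: 3.0, replicated: 3.0}
    protein_altering:
      na: {single: 3.0, replicated: 3.0}
  eqtl:
    lead_qtl_hit:
      brain: {single: 1.0, replicated: 1.5}
      peripheral: {single: 0.5, replicated: 0.75}
    colocalization:
      brain: {single: 2.0, replicated: 3.0}
      peripheral: {single: 1.0, replicated: 1.5}
    twas:
      brain: {single: 1.5, replicated: 2.0}
      peripheral: {single: 0.75, replicated: 1.0}
    fine_mapped_twas:
      brain: {single: 2.5, replicated: 3.5}
      peripheral: {single: 1.25, replicated: 1.75}
  sqtl:
    lead_qtl_hit:
      brain: {single: 1.0, replicated: 1.5}
      peripheral: {single: 0.5, replicated: 0.75}
    colocalization:
      brain: {single: 2.0, replicated: 3.0}
      peripheral: {single: 1.0, replicated: 1.5}
    twas:
      brain: {single: 1.5, replicated: 2.0}
      peripheral: {single: 0.75, replicated: 1.0}
  pqtl:
    lead_qtl_hit:
      brain: {single: 1.0, replicated: 1.5}
      peripheral: {single: 0.5, replicated: 0.75}
    colocalization:
      brain: {single: 2.0, replicated: 3.0}
      peripheral: {single: 1.0, replicated: 1.5}
    twas:
      brain: {single: 1.5, replicated: 2.0}
      peripheral: {single: 0.75, replicated: 1.0}
  mqtl:
    lead_qtl_hit:
      brain: {single: 0.5, replicated: 0.75}
      peripheral: {single: 0.25, replicated: 0.5}
    colocalization:
      brain: {single: 1.0, replicated: 1.5}
      peripheral: {single: 0.5, replicated: 0.75}
    metameth:
      peripheral: {single: 0.5, replicated: 0.75}
  haqtl:
    lead_qtl_hit:
      brain: {single: 0.5, replicated: 0.75}
    colocalization:
      brain: {single: 1.0, replicated: 1.5}
  app_metabolism:
    sirna_hit:
      na: {single: 2.0, replicated: 2.0}
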