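# gutflux

Constraint-based metabolic analysis of gut-microbiome cohorts: who is there,
what can they metabolize, and how does that change in metabolic disease.

Shifts in gut microbial composition accompany obesity, type 2 diabetes (T2D),
and atherosclerotic cardiovascular disease (ACVD), but composition alone does
not say what the community *does*. `gutflux` implements the downstream,
model-based half of such a study for researchers who already have species
(MSP — metagenomic species pan-genome) abundance profiles and species
genome-scale metabolic models (GEMs):

1. **Differential species selection.** Per disease, each species is tested
   case vs control with a two-tailed Wilcoxon rank-sum test; p-values are
   Benjamini-Hochberg adjusted. A species is selected iff FDR < 0.01 *and*
   exactly one group median is 0 while the other is positive; selections are
   pooled across diseases into a deduplicated union. Enrichment direction
   comes from the group means, fold change as log2 with a pseudo-count.
2. **Diet-constrained FBA.** For each selected species model, flux balance
   analysis maximizes biomass flux v_bio subject to S·v = 0 and bounds, with
   exchange lower bounds set to −(diet uptake limit) under anaerobic
   conditions. Exchange fluxes are classified (negative = uptake, positive =
   secretion) and averaged per enrichment group. Model dissimilarity is the
   Jaccard distance on reaction sets, D = 1 − |Ri∩Rj| / |Ri∪Rj| (the
   similarity 1 − D is also exposed).
3. **Reactobiome.** The per-sample reaction abundance is
   RA(s, j) = Σᵢ P(i, j)·a(i, s), the presence-weighted sum of species
   abundances. Reactions are tested per disease (Wilcoxon + BH), intersected
   across diseases, filtered for a consistent enrichment direction and for a
   >20% presence gap between disease- and control-enriched models, and mapped
   to KEGG orthologs.
4. **Personalized community models.** Each sample's top-10 species (by
   abundance, weights renormalized) are merged into one stoichiometric system
   with a shared lumen, a diet-input side, and an output side; species
   biomass fluxes are coupled to abundance weights
   (v_bio,i = wᵢ·v_community) and community FBA maximizes total biomass.
5. **Metabolome association.** Each (reaction abundance, plasma metabolite)
   pair is fitted as metabolite ~ log reaction abundance + age + sex + BMI by
   least squares with BH correction across pairs, and reaction abundances are
   compared between BMI > 30 and BMI < 30 strata by Wilcoxon at raw α = 0.05.

A synthetic-data generator emits functional toy GEMs (shared metabolite
namespace, planted fermentation phenotypes and a tartrate-like marker
subsystem), zero-inflated case/control abundance tables, and plasma
metabolomes with planted associations, so the full pipeline runs offline and
every planted effect is recorded in a truth manifest.

## Worked example

```sh
gutflux run --out demo --seed 17
```

generates the default synthetic study (three cohorts of 60 cases + 60
controls over 40 species) and runs every stage, printing the manifest
summary:

```json
{
 "mean_community_growth": 6.300873864996713,
 "mean_growth_rate_per_h": 5.515620118712901,
 "mean_jaccard_distance": 0.6513107712482399,
 "n_associated_metabolites": 10,
 "n_associated_reactions": 7,
 "n_bmi_significant_reactions": 7,
 "n_community_models": 32,
 "n_consistent_reactions": 15,
 "n_kos": 4,
 "n_models": 40,
 "n_selected_msps_union": 10,
 "n_shared_significant_reactions": 20,
 "n_significant_associations": 70,
 "seed": 17
}
```

Reading it: the two-step rule selects 10 species (exactly the planted
differential set, none spurious); their models grow at 5.5 h⁻¹ on the
anaerobic high-fibre diet and differ with a mean Jaccard distance of 0.65;
20 reactions are significant in all three diseases, 15 of them
disease-enriched everywhere, including all 5 planted tartrate-like marker
reactions; 32 per-sample community models average 6.3 units of biomass flux;
and 70 reaction-metabolite pairs (7 reactions × 10 metabolites, all 10
planted pairs among them) are significant at FDR 0.01, with 7 reactions
higher in the BMI > 30 stratum. Per-stage TSVs and `manifest.json` land in
`demo/`; individual stages are also available as subcommands (`gutflux
generate`, `fba`, `msp-diff`, `reactobiome`, `reaction-diff`,
`community-build`, `community-fba`, `associate`, `bmi-split`).

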