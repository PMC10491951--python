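# interdct

Template-based prediction of protein–protein interface residues by
hierarchical clustering of conservation-weighted interface-mapping profiles,
with docking-based refinement and a calibrated confidence label.

## The problem

Template-based methods are the most accurate way to predict which residues
of a protein form its binding interface — when the right templates are
chosen. Within a fold superfamily (the motivating case is the extracellular
immunoglobulin superfamily) most homolog pairs share less than 35% sequence
identity and bind their partners at diffusely distributed sites, so the
single most important decision is *which subset* of the known complexes to
trust for a given query. `interdct` selects that subset by comparing how
each protein "sees" every template's interface through the lens of residue
conservation.

## The method

Given a library of template complexes (structures with known interfaces) and
a query structure with a precomputed multiple sequence alignment per
protein:

1. **Interface detection.** Interface residues of each template complex are
   found by Voronoi tessellation: two atoms are in contact when their cells
   share a facet and their distance is below the sum of their van der Waals
   radii plus the diameter of a solvent molecule (2.8 Å).
2. **Conservation.** Each protein's per-residue conservation is the
   Jensen–Shannon divergence (λ = ½, log₂) of its alignment columns from a
   background distribution, scaled by the non-gap fraction; scores lie in
   [0, 1].
3. **Mapping matrix.** Every template's interface is transferred onto every
   other protein (and the query) through an iterative sequence-seeded,
   least-squares structural superposition; mapped residues buried below
   5 Å² SASA are discarded. Cell (t, s) of the matrix M holds the residues
   of protein t predicted from template s; the query contributes an empty
   column because its interface is unknown.
4. **Rank clustering.** Each cell is scored by summing the target's
   conservation over the cell's residues restricted to the row's top-8 most
   frequently mapped residues; rows are ranked (1 = highest, average ranks
   on ties), row–row Pearson correlation defines distances d = 1 − r, and
   WPGMA (weighted-average linkage) produces a dendrogram of templates plus
   query.
5. **Subset selection.** Along the root-to-query path, the pair of
   contiguous internal nodes with the largest height gap is found; the
   templates under the lower node are the selected subset.
6. **Consensus (interDCT).** Residues mapped by at least 20% of the subset
   templates with SASA ≥ 5 Å² form the initial prediction. Queries sharing
   more than 35% identity with a template skip clustering: the best template
   (plus any template above 35% and within 20 points of it) is mapped
   directly.
7. **Refinement.** Rigid docked poses of small probe proteins are scored by
   the F₁ overlap of their contact interface with the initial prediction;
   over the best 100 poses, initial residues seen in >50% are kept and
   outside residues seen in >35% are added.
8. **Confidence.** The clustering is repeated 10 times with eight *random*
   residues per cell instead of the top-8; within each alternative subset,
   every member's own interface is re-predicted leave-one-out and scored.
   Template reliability (mean of means) > 0.525 with template inconsistency
   (mean of standard deviations) < 0.175 ⇒ high confidence; both reversed ⇒
   low; otherwise medium.

A fully synthetic fixture generator (`interdct.synthetic`) builds template
families with planted binding patches, conservation-structured alignments,
and docked-pose sets, so the entire pipeline runs and is tested without any
external data or docking engine.

## Worked example

```python
from interdct.synthetic import FixtureSpec, generate_family, make_query, generate_poses
from interdct.library import PredictionContext, InterDCTConfig
from interdct.prediction import predict
from interdct.refinement import refine
from interdct.confidence import assess_confidence
from interdct.evaluation import f_score

family = generate_family(FixtureSpec(seed=1))          # 3 groups x 4 templates
query, truth = make_query(family, group=1, seed=42)    # a 13th family member
ctx = PredictionContext(family.library, query, InterDCTConfig(n_top_poses=20))

pred = predict(family.library, query, context=ctx)
print(pred.path_taken, sorted(k.seq_number for k in pred.residues))
poses = generate_poses(query.structure, truth, 25, 25, seed=7)
refined = refine(query.structure, "A", poses, pred, ctx.config)
print("F =", f_score(refined.residues, truth).f1)
print(assess_confidence(ctx, base_seed=0).label)
```

prints

```
clustered [21, 22, 23, 24, 25, 26, 27, 28]
F = 1.0
high
```

The query shares ~25–30% identity with every template (the nontrivial
regime), so the clustered path runs, selects exactly the query's planted
group, and recovers the planted 8-residue patch; refinement confirms it and
the leave-one-out self-consistency of the selected templates flags the
prediction as high confidence.

There is also a CLI (`interdct simulate / detect / cluster / predict /
refine / confidence / benchmark`) operating on PDB files, FASTA alignments
and a JSON manifest.

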