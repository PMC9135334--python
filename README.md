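# structptm

Structural context for posttranslational modifications (PTMs) on predicted
protein structures.

Predicted proteome-scale structure models cover every residue of a protein —
including intrinsically disordered regions (IDRs) whose coordinates are
essentially arbitrary — and annotate each residue with a confidence score
(pLDDT) and each residue pair with a predicted aligned error (PAE, in Å).
`structptm` turns those models into per-residue structural annotations for
PTM analysis:

* **pPSE (prediction-aware part-sphere exposure).** A generalization of
  half-sphere exposure: for residue *i* with side-chain direction
  *u<sub>i</sub>* = (CB<sub>i</sub> − CA<sub>i</sub>)/‖·‖ (ideal pseudo-CB for
  glycine), residue *j* is counted as a neighbor iff

  ‖CA<sub>j</sub> − CA<sub>i</sub>‖ + max(PAE<sub>ij</sub>, PAE<sub>ji</sub>) ≤ *r*  and  ∠(*u<sub>i</sub>*, CA<sub>j</sub> − CA<sub>i</sub>) ≤ *α*.

  Inflating each distance by the pairwise PAE means residues whose relative
  placement the predictor is unsure about are never counted as packing
  neighbors. Side-chain exposure uses *r* = 12 Å, *α* = 70°; residues with
  pPSE ≤ 5 are classed as highly exposed.
* **IDR and short-IDR calling.** Full-sphere pPSE (*r* = 24 Å, *α* = 180°),
  smoothed along the sequence (±10 residues), flags a residue as disordered
  when ≤ 34.27. Short IDRs — disordered runs of ≤ 20 residues sandwiched
  between structured runs of ≥ 80 residues, optionally extended by 5 residues
  per side — mark flexible linkers and loops embedded in folded domains
  (kinase activation loops being the canonical example).
* **PTM annotation and enrichment.** PTM site tables are filtered to the
  standard acceptor residues per type (p: S/T/Y; ub/sm/ac: K; m: K/R; ga/gl:
  S/T), joined to the structural context, and scored with two-sided Fisher
  exact tests — odds ratio (a·d)/(b·c) over a 2×2 modification-by-category
  table — with Benjamini–Hochberg correction per analysis family.
* **Motif analysis.** Sequence windows (±6 residues, `_`-padded), anchored
  motif matching, and log-odds position-specific scoring matrices, split by
  site exposure with a size-matched random subset of the exposed sites.
* **3D proximity.** PAE-inflated distances d(i,j) = ‖CA<sub>i</sub> −
  CA<sub>j</sub>‖ + max(PAE<sub>ij</sub>, PAE<sub>ji</sub>) feed (a) a global
  binned profile of the fraction of modified acceptors around each modified
  residue versus randomized backgrounds, and (b) a per-protein cluster
  permutation test (mean pairwise distance among modified acceptors vs
  random acceptor draws, empirical p = (1 + m)/(1 + N)). Long IDRs are
  excluded; short IDRs stay in.

A fixtures module generates synthetic structures (ideal helices, disordered
coils, compact globules, multi-segment chimeras) with synthetic pLDDT and
PAE, plus simulated PTM tables, so the entire toolkit runs and is tested
without any external download.

## Worked example

Simulate the standard chimera fixture — two 100-residue folded domains
linked by a 15-residue disordered coil — and call its regions:

```
$ structptm simulate --out fix --seed 1
fix/CHIMERA.pdb
fix/CHIMERA.json
fix/CHIMERA_ptm.tsv

$ structptm short-idr --structure-dir fix --pae-dir fix --out short_idrs.tsv
$ cat short_idrs.tsv
# structptm 0.1.0 config=4e430052e1ad
protein_id	start	end
CHIMERA	104	111
```

The one short IDR (BED-style 0-based half-open, i.e. residues 105–111) sits
inside the 15-residue linker (residues 101–115): smoothing blends the
linker's low neighbor counts with the high counts of the flanking domains,
so only the linker core crosses the disorder threshold — which is exactly
what the extended-region margin is for. Joining the simulated phosphosites
to the structural context:

```
$ structptm annotate --structure-dir fix --pae-dir fix \
      --ptm-table fix/CHIMERA_ptm.tsv --out annotated.tsv
$ head -4 annotated.tsv
# structptm 0.1.0 config=5051fc189f84
protein_id	position	aa	ptm_type	regulatory	ppse_exposure	exposure_class	idr_flag	short_idr_flag	extended_short_idr_flag	eligible_for_proximity
CHIMERA	25	T	p	False	14	low	False	False	False	True
CHIMERA	33	Y	p	False	8	low	False	False	False	True
```

and testing whether phosphosites prefer exposed side chains within the
structured regions:

```
$ structptm enrich --structure-dir fix --pae-dir fix \
      --ptm-table fix/CHIMERA_ptm.tsv \
      --design exposure_high_in_structured --ptm-types p --out enrich.tsv
$ cat enrich.tsv
# structptm 0.1.0 config=29e7766c6c8b
design	ptm_type	protein_id	odds_ratio	p_value	adj_p_value	n_sites	a	b	c	d
exposure_high_in_structured	p		4.26667	0.0788907	0.0788907	11	8	10	3	16
```

The fixture places phosphosites on exposed acceptors five times more often
than on buried ones, and the recovered odds ratio of 4.27 (8 of 18 exposed
acceptors modified vs 3 of 19 buried ones; p = 0.079 at this desk scale)
points the same way. The same library API is available from Python
(`structptm.compute_ppse`, `structptm.call_idr`, `structptm.enrich_in_region`,
`structptm.cluster_test`, …); every CLI output carries the tool version and
a config digest and is byte-reproducible for a fixed `--seed`.

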