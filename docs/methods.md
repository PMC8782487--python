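# Methods

## Model

A protein structure is reduced to an **amino-acid network** *G(t)*: an
undirected graph on residues in which the weight of edge (i, j) counts
the atom pairs — one atom in residue i, one in residue j — at Euclidean
distance strictly below the threshold *t* (Å). The strict inequality is
a fixed convention; atom pairs exactly at *t* do not count. Sequence-
adjacent residues are not treated specially. Which atoms enter the count
is set by the reader's `atom_policy` (default `heavy`, i.e. hydrogens
excluded) because mutagenesis engines may emit hydrogens the deposited
wild type lacks; waters and hetero groups never enter, alternate
locations keep the first-listed conformer, and multi-model files
contribute only their first model.

The **perturbation network** of a mutation is the entrywise absolute
difference of the wild-type and mutant adjacency matrices with all-zero
rows/columns removed. Wild-type and mutant residues are matched by
(chain, residue number, insertion code) only — the mutated residue
changes amino-acid type but keeps its identifier. Four measures
summarise the perturbation: node count, edge count, total weight, and
diameter (hop count). For a disconnected perturbation network the
diameter is taken on the component with the most nodes; if several
components tie, the largest of their diameters is reported, which is
deterministic and reduces to the ordinary diameter in the connected
case. An empty perturbation network reports (0, 0, 0, 0).

## Scores and prediction

Raw measures are processed in a fixed order: (1) average over chains,
so proteins with several identical chains contribute one score per
(position, mutant); when a mutation was scored on a subset of chains
the mean runs over the available ones; (2) remove synonymous entries,
whose identically-zero perturbation would compress the scale; (3)
z-score each (threshold, measure) column with the **population**
standard deviation. Standardizing after chain-averaging makes the unit
of standardization "one mutation", which is also the unit predictions
are made from. Columns with zero spread raise an error rather than
return zeros.

A mutation is *sensitive* for a measure when its z-score is **strictly
greater** than that measure's cutoff (boundary values are not
sensitive; the convention must be fixed for reproducibility and strict
inequality matches the edge-weight convention). A position is a
structurally sensitive position (SSP) when at least `min_count` of the
measures in use have at least one sensitive mutation there; the
remaining scored positions are structurally robust (SRPs). Positions
with no standardized score are excluded from both sets and from all
evaluation denominators. The diameter is excluded from the default
`measures_used` — single-edge changes can swing it wildly — but is
always computed and reported.

Functionally sensitive positions (FSPs) are the ⌊n·percent/100⌋
positions with the lowest mean functional score (default 40%); robust
positions (FRPs) mirror this at the top. Functional scores are used as
published, never standardized. Ties at the percentile boundary resolve
to the lower position number.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `t` (threshold) | 9.0 Å | contact distance; ~9 Å captures structural neighbourhoods rather than chemical bonds and is the recommended operating threshold |
| `cutoffs` | (1.5, 1.5, 1.5) | per-measure sensitivity bar in SD above the mean |
| `min_count` | 2 | measures that must agree for an SSP call |
| `measures_used` | nodes, edges, weight | diameter excluded from prediction |
| `functional_percent` | 40 | FSP/FRP percentile |
| threshold grid | 3.0–10.0 Å, step 0.1 (71 values) | sweep range for correlation/score studies |
| cutoff sweep grid | 1.0–2.0, step 0.02 (51 values) | precision/recall trade-off studies |
| ROC grid | 0.03–3, 100 points | uniform-cutoff sweep for ROC/AUC |

Raising cutoffs or `min_count` strictly narrows the SSP set, trading
recall for precision; the sweep helpers expose this trade-off as tidy
tables.

## Evaluation

With TP = |SSP ∩ FSP| over a universe of N scored positions:
precision = 100·TP/|SSP| (undefined — reported as missing, not 0 —
when nothing is predicted), recall = 100·TP/|FSP|, and the improvement
factor TP·N/(|FSP|·|SSP|), which equals precision/null-precision and
recall/null-recall, where the null values (functional and prediction
percentages respectively) are what independent random prediction would
give. ROC curves use TPR = TP/|FSP| and FPR = FP/(N − |FSP|) — the
standard false-positive-rate denominator — over an ascending cutoff
grid, augmented with the (0,0) and (1,1) corners and integrated by
trapezoid. Per-position Spearman correlations between mean structural
and mean functional scores are reported as absolute values (the raw
correlation is negative: more perturbation, more functional loss); the
two-sided p-value is exact for n < 10, by vectorised enumeration of
rank permutations, and asymptotic otherwise.

## Synthetic data

The generator replaces the two external inputs (a mutagenesis engine
and a published mutational scan) with constructions whose ground truth
is known:

* **Structures** — residue centres on a self-avoiding fixed-step
  (3.8 Å) random walk confined to a sphere of radius 0.7·step·n^(1/3),
  with 5 atoms per residue jittered at SD 1.0 Å. The confinement makes
  the chain a compact globule; without it, chain termini sit in much
  sparser contact neighbourhoods than interior residues, and a global
  z-score cutoff then systematically misses fully disrupted terminal
  positions — an artefact of open-coil geometry, not of the method.
* **Mutants** — a copy of the wild type with one residue's atoms
  displaced in random directions. The magnitude is the nominal
  displacement (2.0 Å, a rotamer-scale rearrangement) times a severity
  factor 1.75·U(0,1)² drawn per mutant: most substitutions are
  structurally mild, a few severe, mirroring the spread seen in real
  saturation mutagenesis. With a constant magnitude instead, all
  disruptive mutants of a 40%-disrupted protein score identically at
  √((1−p)/p) ≈ 1.2 SD above the pooled mean and no mutation can clear
  a 1.5 SD cutoff — the severity spread is what makes the worst mutant
  at a position informative.
* **Functional tables** — entry (position, mutant) = effect(position)
  + N(0, 0.1), with synonymous cells at 0 and effect −2 at a designated
  40% of positions, 0 elsewhere. The effect is a function of position
  alone, which is the empirical structure of deep-mutational-scanning
  data this pipeline targets.

All generators are deterministic given the seed (a seed sequence keyed
by generator and mutant, so datasets are reproducible bit for bit).

What passing the end-to-end recovery test shows: the pipeline's
plumbing — network construction, differencing, chain handling,
standardization, thresholding, evaluation — is internally consistent
and recovers a clean position-dependent signal through the full stack.
What it does not show: performance on real proteins, where side-chain
repacking is not isotropic displacement, structural and functional
sensitivity correlate imperfectly, functional-score distributions are
irregular, and precision/recall land far below 100%. The five-protein
scale of a real study (hundreds of positions × 19 mutants × 71
thresholds) is likewise reduced here to a 30-residue chain at one or
three thresholds so the whole suite runs in seconds.

## Numerical choices

* Atom-pair search uses a k-d tree at the largest requested threshold;
  per-threshold networks reuse the cached pair distances.
* Edge weights, measures and adjacency matrices are integers; z-scores
  and everything downstream are floats.
* The ROC cutoff grid must be ascending; duplicate (FPR, TPR) points
  are harmless under trapezoid integration.
* Degenerate cases raise rather than guess: empty structures,
  non-positive thresholds, mismatched threshold pairs, zero-spread
  columns, percentile selections of size zero, constant vectors in a
  correlation, all-or-nothing ROC references.
* `scikit-learn` is used only in tests, as an independent check of the
  trapezoid AUC.

## Limitations

Mutant structures are consumed, not produced: a mutagenesis engine (or
the synthetic generator) must supply them, and the quality of its
models bounds the quality of the scores. Only standard amino acids are
modelled; ligands, cofactors, nucleic acids and waters are invisible to
the networks. mmCIF input is not supported. The diameter's behaviour on
disconnected perturbation networks follows the convention above and
other conventions would give different values on multi-component
networks.
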