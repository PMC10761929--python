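# Methods

## Evidence weighting of interaction records

Interaction databases attach one or more PubMed IDs to each reported pair.
Let n(p) be the number of distinct canonical pairs supported by
publication p within the analyzed table. The publication weight is
w(p) = n(p)^(−1/2) and a pair's score is Σ w(p) over its distinct
supporting publications. Candidates are pairs with score ≥ 0.3
(inclusive): the boundary sits between a single publication reporting 11
interactions (1/√11 ≈ 0.3015, candidate) and 12 (1/√12 ≈ 0.2887, not).

Choices where the convention was open:

* Unordered pairs are canonicalized lexicographically; self-interactions
  (A–A) are retained but can be dropped (`include_self=False`), since
  self-pairs are meaningful for homodimers but often artifacts.
* n(p) counts distinct pairs, not raw rows — row duplication (e.g. the
  same pair reported in both orders) is a database artifact.
* A publication supporting the same pair via several rows contributes its
  weight once.
* n(p) is computed genome-wide within the provided table, not only among
  driver-touching rows; this matches how a database-wide export would be
  weighted and is the only computable convention when the table is the
  whole input.

## Paired MSA assembly

Per target protein and organism one ortholog is kept: identity strictly
above 35% and e-value ≤ 0.001, then the survivor with the highest
similarity. The similarity statistic is taken from the hit table as
provided (bit score by convention; any monotone similarity works), with
sequence-id as a deterministic tie-break. Homology search, clustering and
alignment themselves (BLAST/CD-HIT/MAFFT) are consumed as inputs — hit
tables and FASTA/A3M alignments — not executed here.

Alignment columns that are gaps in the target are removed from all rows,
making the alignment length equal the target's ungapped length (an
idempotent operation). The joint MSA concatenates same-organism rows;
organisms present in only one alignment are appended after the paired
block, gap-filled in the missing block, msa1-only rows before msa2-only
rows, each preserving input order. The 200-residue inter-chain gap is
realized as a residue-index offset (chain-2 residue i numbered
L1 + 200 + i) recorded in a sidecar index map; a `literal_gap` flag emits
it as gap characters instead, since serializations differ between
modeling front-ends. Pairs with combined length ≤ 1500 pass the direct
modeling gate; longer ones are enumerated as domain-pair cross products
with over-limit pairs flagged. Domain boundaries are inputs (ranges), not
computed: parsing domains from monomer models is a separate concern with
its own literature.

## Distogram contact scoring

Distance-bin logits of shape (L, L, 64) are softmax-normalized per residue
pair (scipy's stable implementation). The 64 bins are equal-width over
2–22 Å (0.3125 Å each), so bins 1–32 end exactly at
2 + 32 × 0.3125 = 12 Å; the contact probability is the sum of those first
32 bins. The last bin is treated as closing at 22 Å per the equal-size
convention — real networks leave it open-ended, but the score only uses
bins 1–32, so this matters solely to fixture builders. The inter-protein
block m′ = m[0:L1, L1:L1+L2] is extracted and its maximum (row-major
first-hit tie-break, 1-based per-chain argmax) is the pair score;
high confidence means score strictly > 0.9. Domain-pair scores aggregate
to a protein score by max, and both the per-domain-pair and
post-aggregation counts of the 0.9 gate are available, since either
granularity can be the relevant unit of reporting.

## Interfaces and mutation mapping

Contacts are inter-chain residue pairs with distance strictly < 8 Å. The
default atom convention is the minimum over all heavy-atom pairs — the
common interface definition and the more inclusive reading — with a
`c_beta` mode (Cα for glycine, Cα fallback when Cβ is absent) as the
alternative; heavy-atom contact sets are supersets of Cβ sets at the same
cutoff. Waters and non-polymer het groups are excluded; modified residues
with a known parent (MSE, HYP, SEP, TPO, PTR, ...) are mapped to the
parent name. A chain pair qualifies as an interface at ≥ 10 contacts.

Mutation positions are 1-based canonical-sequence coordinates reconciled
to author numbering via an explicit per-gene (chain, offset) table — no
automatic alignment-based renumbering, so disagreements surface instead
of being silently absorbed. A mutation is `matched` when its mapped
residue is an interface residue; `ref_consistent` compares the mutation's
reference amino acid to the structure's residue and mismatches are
flagged, never dropped.

## ΔΔG classification

ΔΔG (kcal·mol⁻¹, positive destabilizes binding) comes from external
energy-function runs or the generator; the energy function is not
re-implemented. Bands: ΔΔG > 1.4 destabilizing (strict); 1.0 < ΔΔG ≤ 1.4
possibly destabilizing; −1.0 ≤ ΔΔG ≤ 1.0 neutral; ΔΔG < −1.0 stabilizing
(the conventional stabilizing threshold). Boundaries are closed on the
neutral side and configurable. The thermodynamic context defaults to
R = 1.987 × 10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298 K ("room temperature");
298 vs 298.15 K both give RT·ln 10 = 1.36 kcal·mol⁻¹ at two decimals,
which is why 1.4 corresponds to slightly more than a 10-fold affinity
change. Fold change is exp(ΔΔG/RT), strictly increasing and exactly
invertible. Cohort summaries count and fraction each band per complex and
overall; denominators are mapped mutations (rows present in the input) —
a mutation hitting several interfaces contributes one row per
mutation–complex pair.

## Benchmarking

Rankings are score-descending with ties broken by canonical pair name, so
curves are reproducible under permutation of the input. The support curve
at k is |top-k ∩ reference|; reference support (e.g. PDB coverage) is an
input label set because determining it is external and version-dependent.
Default reporting points are k ∈ {50, 100, 200, 1000}. Three-way overlap
is reported as the seven Venn regions; per method the four regions
containing it sum to k. External methods' confidence metrics are ingested
as score tables, not re-implemented.

## Synthetic data: what it emulates and what it does not

* **Interaction tables** — publication sizes are ⌈exp(N(1.0, 1.5))⌉,
  clipped to the pair universe: a heavy-tailed mix of focused studies and
  screens, which is the regime that motivates the weighting. True scores
  are computed analytically from the planted assignments. Defaults:
  300-pair universe, 120 publications.
* **Distograms** — per residue pair the bin mass is split so that the
  first-32-bin sum equals a planted probability (background pairs get
  0.01–0.08), with random within-half composition; logits are
  log-probabilities. The log/exp round trip through the scoring softmax
  perturbs the planted mass by O(10⁻¹⁶); the generator resolves this
  roundoff downward (a short Newton correction on the planted pair's
  near-bin logits) so a value planted exactly at a strict threshold never
  crosses it. Default size 50+50 residues.
* **Toy complexes** — two parallel chains of Ala pseudo-residues (Cα/Cβ
  only, sufficient for both atom modes), 10 Å apart along the chain so
  that exactly the first k facing pairs (at 5 Å) are contacts and the
  closest non-facing pair is √(10² + 5²) ≈ 11.2 Å; the count is exact by
  construction, not rejection sampling. A random-scatter variant exists
  for oracle comparisons against an O(n²) distance scan.
* **ΔΔG cohorts** — band counts are allocated exactly (default
  268 destabilizing, 88 possibly destabilizing, 640 neutral of 996, the
  shape of a realistic mapped-mutation cohort) and values drawn uniformly
  within band-interior intervals, so classification recovers the planted
  labels exactly.
* **Method scores** — each method scores c·q + (1−c)·noise with latent
  quality q and concordance c (default 0.8); c = 1 gives identical
  rankings and expected top-k overlap grows monotonically with c. The
  supported reference set is drawn with probability proportional to q.

What passing on this data does **not** show: real MSAs have phylogenetic
structure and alignment error; real distograms have spatially correlated
contact patterns rather than independent per-pair masses; real interfaces
have side-chain packing that the Cα/Cβ toys lack; real ΔΔG distributions
are not uniform mixtures. The generators validate bookkeeping, thresholds
and numerical behavior of the pipeline, not the biological accuracy of
any upstream predictor.

All generators take a single seeded NumPy generator per invocation
(independent streams per generator, derived from the config seed) and are
byte-deterministic under a fixed seed.

## Problem sizes

Tests and the acceptance script run the generators at their default
sizes — 50+50-residue distograms, 30-residue toy chains, a 300-pair
universe, the 996-mutation cohort — which exercise every code path in
seconds on one CPU while keeping oracle comparisons (exhaustive distance
scans, brute-force set algebra) exact.

## Known limitations

* Bioassembly expansion is delegated to the structure parser; only the
  chains present in the file are analyzed.
* No homology transfer of mutations across species and no
  alignment-based renumbering; offsets must be supplied.
* The benchmark treats reference support as a given label set; absolute
  support counts from a live structural database are version-dependent
  and out of scope.
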