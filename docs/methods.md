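# Methods

## The problem and the model

`trioprio` prioritizes candidate disease variants from trio WGS of an
affected child and two unaffected parents. The analysis assumes a monogenic
(or at least strongly driven) architecture compatible with the pedigree:
because both parents are healthy, autosomal dominant inheritance is off the
table, leaving X-linked recessive (hemizygous in a male proband, carrier
mother), autosomal recessive (homozygous child, carrier parents), and de
novo variation. All genotype logic is evaluated through the pedigree;
"present" always means a non-missing call carrying at least one alternate
allele.

The pipeline deliberately separates two orthogonal notions of evidence:

* **contextual evidence** — the gene sits near known disease genes in a
  functional interaction network (branch 1);
* **intrinsic evidence** — the variant itself is predicted damaging by
  sequence/structure predictors (branch 2).

Branch 1 is gated on population rarity (< 0.1% in the ancestry-matched
panel), branch 2 is not. The union of both branches therefore retains
variants that are damaging yet not rare in the matched population — the
scenario the design exists for.

## Stage-by-stage assumptions and parameters

**Relatedness check.** SNP concordance (fraction of autosomal SNV sites
where a sample pair shares ≥ 1 allele index) over all fully called sites;
parent–proband values below `relatedness.flag_threshold` (default 0.5) warn
but never abort, since the check exists to catch sample swaps, not to gate
biology. `min_sites` defaults to 100.

**Site hard filters.** The five standard site-level metrics with the
conventional cutoffs: QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0. Comparisons are strict, so a value exactly at a
threshold survives; an absent metric can never fail a variant. A published
variant of the FS rule ("FS > 60 or FS > 200") is logically redundant — the
first clause subsumes the second — so a single `fs_max = 60.0` is
implemented.

**Inheritance modes.** The presence rules are exhaustively enumerable and
tested against hand-verified truth tables (27 autosomal, 12 chrX
combinations). The autosomal-recessive parental constraint defaults to the
strict trio model (both parents heterozygous); `inheritance.recessive_model:
relaxed` accepts any carrier parent that is not homozygous-alt. Modes may
co-occur except DE_NOVO/AUTOSOMAL_RECESSIVE, which are exclusive by
construction. All of chrX is treated as hemizygous territory for a male
proband; `inheritance.par_exclude` optionally exempts the hg19
pseudoautosomal regions. A diploid heterozygous call on male chrX (callers
disagree on X ploidy) counts as present and is provenance-tagged
`XHET_MALE`.

**Impact selection.** SO consequence terms map to HIGH / MODERATE / LOW /
MODIFIER through a packaged, versioned, user-overridable table following the
common annotator convention; HIGH + MODERATE are retained by default.
Unknown terms are kept (conservatively, with a warning tag); unannotated
variants are dropped because they cannot be classified functionally
important.

**Frequency filters.** Panel maxima: dbSNP GMAF 5%, 1KGP 2%, ExAC 5%,
gnomAD-AJ 5%; the branch-1 rare gate is AJ < 0.1%, strict. Absent
frequencies never exclude (novel alleles survive); frequencies are consumed
as given, with no minor-allele folding.

**Network propagation.** Direct-neighbor scoring is the exact edge-weight
sum to the seed set. The diffusion score is the unique minimizer of

    (1−α)/α · Σᵢ (fᵢ − yᵢ)² + Σ₍ᵢⱼ₎ w′ᵢⱼ (fᵢ − fⱼ)²

equivalently `f = (1−α)(I − αS)⁻¹y` with `S` the symmetrically
degree-normalized weight matrix — the standard closed form for
graph-regularized label smoothing. It is computed by the fixed-point
iteration `f ← αSf + (1−α)y` (spectral radius of αS < 1 guarantees
convergence) to max-abs residual `propagation.tol = 1e−10`, capped at
10,000 iterations; non-convergence is fatal. α defaults to 0.8 (scores
spread several hops but stay seed-anchored); isolated nodes receive
`(1−α)yᵢ`. Ranks over non-seed genes use competition ranking (ties share
the best rank) with a deterministic secondary sort on gene symbol. One
property worth noting: with degree normalization, diffusion scores on trees
decrease monotonically along every path away from a single seed, but there
is no global ordering by hop distance across branches — a deep node in a
low-degree chain can legitimately out-score a shallower hub.

**Network support rule.** A branch-1 candidate gene counts as
network-supported if it has any direct seed contact (direct > 0) or a
diffusion rank in the top `selection.q` fraction of non-seed genes (default
0.10; `q = 0` disables the diffusion route). The rule is a configurable
predicate, and both scores and ranks are always emitted so users can apply
their own cutoff.

**Pathogenicity branch.** A "possibly damaging SNV" requires both
predictors present and damaging: SIFT ≤ 0.05 and PolyPhen-2 ≥ 0.447 (each
tool's canonical published threshold; both configurable). Ranking uses
`combined = polyphen + (1 − sift)` — a monotone, scale-free merge of the two
evidence directions, in [0, 2] — with ties broken by lower SIFT then gene
symbol; the top `pathogenicity.k = 2` are kept.

**Finalization.** Manual disease-relevance review is modeled as data (a
gene → reason exclusion list), keeping an honest boundary between computed
and curated steps. Zygosity outcomes: WILD_TYPE ⇒ false positive (drop);
HETEROZYGOUS on a recessive or male-X candidate ⇒ inconsistent (drop);
otherwise consistent observations confirm; ungenotyped candidates remain
UNTESTED and retained — absence of orthogonal genotyping is not evidence
against. Final ranking: CONFIRMED before UNTESTED; within a group,
BOTH-workflow provenance first, then descending combined score (absent
sorts last), then descending diffusion, then gene symbol.

## The synthetic-data generator

The generator emulates the statistical structure of a single-trio WGS study
whose raw data cannot be shipped. Defaults (chosen once as a realistic
desk-scale study): 400 autosomal + 120 chrX background sites, latent allele
frequencies Beta(0.3, 2.5) (rare-skewed), per-panel frequencies derived
from the shared latent truth with independent log-normal noise (σ = 0.3) so
multi-panel filters behave realistically rather than leaking, 10% of sites
drawn with ≥ 1 QC violation (violating values strictly beyond the cutoff,
passing values inclusive of it), 2 injected autosomal de novos, and a
200-node preferential-attachment network (m = 2) with edge weights in
(0.7, 1] and 20 seed genes.

Parental genotypes are Hardy–Weinberg draws from the latent frequency;
proband genotypes are Mendelian transmissions (haploid maternal X for the
male proband). The planted causal variant mirrors the headline case:
X-linked, hemizygous proband, carrier mother, AJ frequency 0.02 (too common
for the branch-1 gate), SIFT 0.01 / PolyPhen 0.95, in a gene wired to two
seed genes. Four distractor genes carry rare, benign, X-linked missense
variants and hang on dedicated 2-filler chains, guaranteeing ≥ 3 hops from
every seed (checked by BFS at generation time), so they reach branch 1 but
earn no direct-neighbor support.

All randomness flows from `numpy.random.Generator` streams derived from
`(seed, domain-tag)`; a fixed configuration is byte-reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium and haplotype structure,
genotyping error and genotype-likelihood uncertainty, indel/multi-nucleotide
complexity at scale, realistic gene-symbol vocabularies and annotation
noise, segmental duplications or other systematic QC-failure clustering,
and the million-fold larger site counts of real WGS. The end-to-end recovery
result demonstrates the logic of the funnel, not calling accuracy.

## Numerical and engineering choices

* Strict inequalities exactly as printed for every threshold; equality
  survives.
* Floats in VCF INFO are written with full `repr` precision; after one read
  through the VCF layer (which stores INFO floats at single precision) the
  representation is stable, so read∘write∘read is the identity.
* Multi-allelic records split at ingest; an allele pointing at a different
  alt than the split record carries maps to 0 for that record; site-level QC
  metrics are copied to each split.
* STRING-style 0–1000 scores are auto-detected (any value > 1) and divided
  by 1000, preserving the strict `> 0.7` confidence semantics across
  dialects.
* Deterministic output everywhere: sorted iteration orders, competition
  ranks with symbol tie-breaks, byte-stable writers; two runs of the same
  config produce identical bytes.
* Problem sizes in tests and the acceptance script (10,000-site filter
  recounts, 100-replicate recovery, ≤ 50-node oracle graphs) were chosen as
  the smallest sizes at which the properties are meaningfully exercised.

## Known limitations

* No compound-heterozygote, mitochondrial, or imprinting models; no
  genotype-quality (GQ/DP) filters beyond the five site metrics.
* The de novo rule is the pedigree presence rule only; no calling from
  likelihoods.
* The network-support selection rule and the combined pathogenic score are
  reasonable defaults for decisions that real studies make partly by
  judgment; both are exposed in config rather than hidden.
* SIFT/PolyPhen scores and SO consequences are consumed as annotations,
  never computed.
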