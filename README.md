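# reef-assembly

Trait- and phylogeny-based community assembly analysis for nested
(atoll / site / coral-colony) sampling designs.

The package apportions Rao's quadratic entropy (QE) additively across the
three spatial scales of an unbalanced nested design with even weighting at
every level, and tests each beta component against a scale-specific
permutation null via the standardized effect size
`SES = (observed − null mean) / null sd` (positive = clustering, negative =
over-dispersion). The same machinery runs with trait distances (TQE, Gower
on mixed quantitative/nominal traits) and with genetic distances (PQE, raw
p-distance per gene or over a gene concatenation), including a per-gene
robustness summary against the consensus matrix. Phylogenetic signal is
measured with Blomberg's K (optionally folding in intraspecific sampling
error through a one-parameter ML fit) and, for nominal traits, the
Maddison–Slatkin parsimony randomization test. A fecundity trait is built
from egg counts and egg dimensions (prolate-spheroid volumes, counts
rescaled by relative egg volume) and interpolated from body size by a
log–log power-law fit. A fully seeded synthetic-data module generates Yule
trees, Brownian/Mk traits, gene-distance proxies and nested metacommunities
under neutral, environmental-filtering and limiting-similarity regimes, so
the whole pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `reef_assembly.data_io` | Newick / aligned-FASTA / trait-CSV / community-CSV readers, cross-validation of the four artifacts |
| `reef_assembly.distances` | Gower, per-gene and concatenated p-distance, patristic distance, Euclidean-embeddability check |
| `reef_assembly.diversity` | QE, even-weight pooling, three-scale apportionment, per-level permutation SES tests, report grid |
| `reef_assembly.signal` | phylogenetic covariance, Blomberg's K (± measurement error), Fitch steps, Maddison–Slatkin |
| `reef_assembly.traits` | egg volume, size-adjusted fecundity, power-law interpolation |
| `reef_assembly.synthetic_data` | Yule trees, BM/Mk traits, gene-distance proxies, nested metacommunity scenarios |
| `reef_assembly.pipeline` | one-command orchestration and consolidated JSON/CSV reports |

## CLI

```sh
# full analysis from a YAML config (paths, n_perm, seed, ...)
reef-assembly run --config config.yaml

# generate a synthetic scenario (tree.nwk, traits.csv, community.csv, truth.json)
reef-assembly simulate --config scenario.yaml --out scenario/

# distance matrices and QE apportionment as standalone steps
reef-assembly distances --tree tree.nwk --kind patristic --out D.csv
qe-apportion --community community.csv --distance D.csv --level all \
             --nperm 999 --seed 42 --out report.json

# phylogenetic signal
phylosignal k --tree tree.nwk --traits traits.csv --trait carapace_length \
              --se from-individuals --nperm 999 --seed 7
phylosignal discrete --tree tree.nwk --traits traits.csv --seed 7
```

Example pipeline config:

```yaml
tree: tree.nwk
traits: traits.csv
community: community.csv
alignments: [16S.fasta, enolase.fasta]
n_perm: 999
seed: 42
halve_distances: false
fecundity_mode: both
out_dir: out/
```

All randomness flows through explicit seeds; identical config + seed gives
a byte-identical report.

## Permutation nulls

Each spatial level is tested against a null that breaks structure only at
that level:

* **colonies within sites** — each site's individuals are pooled and
  reallocated at random to its colonies, preserving colony sizes;
* **sites within atolls** — colonies are reassigned at random to sites
  within their atoll, preserving each site's colony count;
* **atolls** — whole sites (with their colonies) are reassigned at random
  to atolls, preserving each atoll's site count.

P-values are two-sided around the null mean with the +1 correction; an SES
with zero null spread is reported as undefined (`null`), never coerced to 0.

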