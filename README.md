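# poolforge

Random pools of short RNA oligomers are not inert: activated (or even plain)
pools spontaneously ligate and recombine, disproportionating into longer and
shorter molecules and — counterintuitively — *gaining* sequence diversity.
`poolforge` is a toolkit for studying this behaviour computationally, aimed at
researchers analysing deep-sequencing data of ligation/recombination products
from random or semi-random oligonucleotide pools, and at anyone modelling the
information dynamics of prebiotic polymer populations.

It provides two connected components:

1. **A stochastic hydrolysis–ligation simulator with diversity accounting.**
   A pool is a multiset of sequences. In one recombination round each molecule
   of length *L* is cleaved with probability *h* at a bond drawn from
   𝒩(*L*/2, σ), and fragments longer than 2 nt then ligate with probability
   *ℓ* to partners drawn from the fragment and survivor populations in
   proportion to their sizes. Information content is tracked with the Shannon
   diversity index

   *D* = −Σᵢ nᵢ log₂ nᵢ,

   where nᵢ is the proportion of molecules carrying the *i*-th unique
   sequence; Δ*D* = *D*₍after₎ − *D*₍before₎ is mapped over a grid of
   (*h*, *ℓ*) rates.

2. **A sequencing-product analysis pipeline**, fully testable on synthetic
   reads: FASTQ quality filtering ("90% of bases at Q ≥ 20"), read collapsing,
   constant-flank trimming and product-size splitting; position-specific
   nucleotide frequency profiles and their RGB colour signatures
   (R = 255(1−f_C−f_A), G = 255(1−f_C−f_U), B = 255(1−f_A−f_G−f_U));
   ligation-junction dinucleotide fingerprints (the CpN bias of RNA pools)
   with log2 enrichment against the unligated input pool; matched-frequency
   synthetic pool generation; secondary-structure profiles over dot-bracket
   sets with an internal base-pair-maximization folder and a pluggable
   external MFE backend (e.g. RNAfold); junction-proximal structure-submotif
   scanning with PWM consensus extraction; exact pool combinatorics; and
   pseudo-first-order ligation-kinetics fitting.

The `synthetic_data` module generates bait × prey concatenation products with
a tunable junction-dinucleotide bias and truncation ladder, carrying full
truth annotation, so every analysis stage is validated by parameter recovery.

## Worked example

```python
import poolforge as pf

# a 10^15-member eicosamer pool, analytically
pf.pool_combinatorics(10**15, length=20, alphabet_size=4)
# {'diversity': 1099511627776, 'binary_pairs': 1208925819614629174706176,
#  'redundancy': 909, 'amount_nmol': 1.6605390671738467}
```

Each possible 20-mer is present in 909 copies, the pool weighs in at about
1.7 nmol, and its pairwise interaction space exceeds 10²⁴.

```python
# one recombination round on a redundant N20 pool (1000 uniques x 100 copies)
pool = pf.make_pool(pf.PoolSpec(length=20, n_unique=1000, redundancy=100), seed=1)
out = pf.simulate_recombination(pool, pf.SimParams(hydrolysis_rate=0.5,
                                                   ligation_rate=0.5, seed=2))
print(f"D before {out.D_before:.2f} -> after {out.D_after:.2f} bits "
      f"(delta {out.delta_D:+.2f})")
# D before 9.97 -> after 14.73 bits (delta +4.77)
```

Recombination of the redundant pool *raised* the Shannon diversity by about
5 bits: cleavage and religation create new sequence species faster than they
merge existing ones whenever the pool carries redundancy. A full rate grid is
one call (`pf.delta_D_grid`) or one shell command:

```bash
poolforge simulate --n-unique 1000 --redundancy 100 \
    --h-rates 0.2,0.6,1.0 --l-rates 0.2,0.6,1.0 --replicates 5 \
    --seed 1 --out grid.tsv
# grid minimum mean delta-D: 2.3623 bits -> grid.tsv
```

Every cell is positive: under these conditions diversity grows for all
examined rate combinations. The full pipeline (pool → products → reads →
profiles → fingerprints → structures → motifs → grid) runs end-to-end with
`poolforge all --seed 1 --out demo_out`, writing TSV tables and a
checksummed manifest.

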