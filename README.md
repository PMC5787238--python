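# smurf

Joint high-resolution profiling of microbial communities from **multiple
independently amplified 16S rRNA gene regions**.

Short-read amplicon surveys usually sequence a single variable region of the
16S rRNA gene, so many bacteria share the same amplicon and cannot be told
apart. This package reconstructs one coherent community profile from any
number of short amplified regions: the de facto amplicon is the union of all
regions, which sharply reduces the number of full-length reference sequences
("the ambiguity") compatible with each profiled organism — without long-read
sequencing or non-standard library preparation.

## The model

Every reference sequence *j* is represented by the read-length k-mers it
would produce from each PCR-amplified region (one concatenated
forward‖reverse k-mer per region for paired-end reads). A sparse mixture
matrix *M* holds *M*<sub>hj</sub> = Pr(kmer = h | bacterium = j) = 1/*R*<sub>j</sub>
(paired-end), where *R*<sub>j</sub> is the number of regions amplified for
*j* under a ≤ 2-mismatch primer rule. Each retained unique read *i* is
matched to same-region k-mers with

E<sub>ih</sub> = (p<sub>e</sub>/3)<sup>n<sub>e</sub></sup>·(1 − p<sub>e</sub>)<sup>L − n<sub>e</sub></sup>,  n<sub>e</sub> ≤ 2,

(p<sub>e</sub> = 0.005 per base by default). With
Q<sub>ij</sub> = Σ<sub>h</sub> E<sub>ih</sub>M<sub>hj</sub>, the likelihood
Π<sub>i</sub> Σ<sub>j</sub> Q<sub>ij</sub>π<sub>j</sub> is concave in the
read-proportion vector π on the simplex, and the EM fixed point

π<sub>j</sub><sup>(t+1)</sup> = π<sub>j</sub><sup>(t)</sup> · (1/N) · Σ<sub>i</sub> Q<sub>ij</sub> / Σ<sub>j′</sub> Q<sub>ij′</sub>π<sub>j′</sub><sup>(t)</sup>

converges to the global optimum. Frequencies are
x<sub>j</sub> = (π<sub>j</sub>/R<sub>j</sub>) / Σ(π<sub>j</sub>/R<sub>j</sub>).
Sequences sharing identical k-mers over every amplified region form a
*group*; per-organism resolution is reported as the exponent of the Shannon
entropy of the group-weight vector (the effective number of assigned
full-length sequences — lower is better).

## Worked example

A 200-sequence synthetic reference in which the first region is shared in
blocks of ten (so one region alone cannot resolve it), profiled from a
simulated 30-member power-law community with 5,000 reads and a 0.5% error
rate:

```python
from smurf.reference_db import build_region_kmer_db, compute_theoretical_groups
from smurf.profiling_core import ErrorModel, profile
from smurf.read_processing import apply_low_frequency_filter
from smurf.simulation_eval import (
    toy_primer_set, toy_reference, sample_power_law_community,
    simulate_region_reads, weighted_precision_recall)

primers = toy_primer_set(n_regions=3, seed=5)
ref = toy_reference(200, primers, seed=6, region_pool_sizes={1: 20})
db = build_region_kmer_db(ref, primers, k=20, mode="paired")

for subset in ([1], [1, 2, 3]):
    fp = compute_theoretical_groups(db, subset)
    print(f"regions {subset}: {fp.n_groups} groups, "
          f"unique fraction {fp.unique_fraction():.2f}")

community = sample_power_law_community(ref, n=30, seed=42)
reads = apply_low_frequency_filter(
    simulate_region_reads(community, db, total_reads=5000,
                          error_rate=0.005, seed=42), 1e-4)
result = profile(reads, db, ErrorModel(p_e=0.005))
ev = weighted_precision_recall(community, result, ref)
print(f"weighted recall:    {ev.recall:.3f}")
print(f"weighted precision: {ev.precision:.3f}")
```

prints

```
regions [1]: 20 groups, unique fraction 0.00
regions [1, 2, 3]: 200 groups, unique fraction 1.00
weighted recall:    1.000
weighted precision: 1.000
```

With one region the 200 references collapse into 20 indistinguishable
groups and the same reconstruction reaches a weighted precision of only
0.294 (mass is spread over whole groups); with all three regions every
sequence is uniquely identifiable and the community is recovered exactly.
The same operations are available from the shell:

```bash
smurf build-db --fasta ref.fasta --taxonomy tax.tsv --read-len 75 --out DB
smurf prep --fastq r1.fastq --fastq2 r2.fastq --read-len 75 --out reads.tsv
smurf profile --db DB --reads reads.tsv --out profile.tsv
smurf resolve --profile profile.tsv --db DB
smurf run --config config.yaml        # all stages, one manifest
```

The packaged default primer table is the six-pair set spanning ~80% of the
16S gene; a standard degenerate V4 pair ships alongside it.

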