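# kmerank

Rank database strings by the percent of unique k-mers they share with a
query.  `kmerank` builds an on-disk inverted k-mer index over a FASTA
string database — DNA, RNA, protein, or arbitrary text — and scores
queries with

```
similarity = 100 * |shared unique k-mers| / min(|Q k-mers|, |S k-mers|)
```

so repeats count once and homopolymer-length errors never change a
score.  It also ships a ROC-calibration utility for choosing a k-mer
size and a similarity cutoff against alignment-identity labels, and a
deterministic synthetic-fixture generator so everything is testable
offline.

## CLI

```sh
# build an index (one file per database + k combination)
kmerank format db.fasta -k 7 --alphabet dna --out db.srdb

# search queries (defaults: top 10 hits with >= 90% similarity)
kmerank search db.srdb queries.fasta --alphabet dna --out hits.tsv

# calibrate a similarity cutoff against alignment-identity labels
kmerank calibrate --hits hits.tsv --identities identities.tsv \
    -k 7 --identity-threshold 0.97 --target-tpr 0.95 --out roc.tsv

# generate deterministic synthetic inputs
kmerank fixtures random --n 100 --length 200 --seed 1 --out syn.fasta
kmerank fixtures family --n 8 --length 500 --identity 0.97 --seed 1 \
    --out fam.fasta --identity-out fam_ident.tsv
```

Exit codes: 0 success, 1 usage error, 2 data/format error.  Hit tables
are TSV with a `#`-prefixed provenance header; columns are
`query_id, subject_id, percent (two decimals), shared, query_unique,
subject_unique`, and queries without hits emit a placeholder row with
`-` in the subject fields.

Notes:

- No case folding is applied anywhere unless you pass `--fold-case`;
  text payloads are compared byte-for-byte.
- An index stores exactly one k; searching with a different `-k` is an
  error.  Alphabet restriction (e.g. `--alphabet dna`) drops any window
  containing a character outside the set.
- Sequence payload lines keep their interior spaces (meaningful for
  text-mode databases); write text records unwrapped.

## Index file format

The `.srdb` binary layout (eleven segments, delta-encoded posting
lists, seek-based posting retrieval) is documented with a worked hex
dump in [docs/format.md](docs/format.md).  Search start-up reads every
segment except the posting arrays themselves, which are fetched lazily
per query k-mer.

## Library

```python
from kmerank import (build_index, write_index, read_header,
                     search_batch, SearchParams, DNA)
from kmerank.sequence_io import read_fasta

records = read_fasta("db.fasta")
write_index(build_index(records, 7, DNA), "db.srdb")
view = read_header("db.srdb")
with view:
    for result in search_batch(read_fasta("q.fasta"), view,
                               SearchParams(top_n=10, min_percent=90),
                               alphabet=DNA):
        for hit in result.hits:
            print(result.query_id, hit.subject_id, f"{hit.percent:.2f}")
```

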