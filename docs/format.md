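# The `.srdb` index file format

A `.srdb` file is the on-disk inverted k-mer index produced by
`kmerank format` and consumed by `kmerank search`.  It consists of
eleven segments in fixed order.  Notation: `F` = string-ID field width
in bytes, `K` = k-mer length, `N` = number of database strings,
`k` = number of distinct k-mers, `P` = total posting entries
(`P == sum of per-string unique k-mer counts`).

| seg | contents                                              | bytes |
|-----|-------------------------------------------------------|-------|
| 1   | `F`, ASCII decimal, left-padded with spaces           | 10    |
| 2   | `K`, same encoding                                    | 10    |
| 3   | `N`, same encoding                                    | 10    |
| 4   | string identifiers, right-padded with spaces to `F`   | F·N   |
| 5   | delta-encoded posting ("offset") arrays, concatenated | 4·P   |
| 6   | distinct k-mers, `K` bytes each, ascending byte order | K·k   |
| 7   | absolute file position of each posting array          | 4·k   |
| 8   | element count of each posting array                   | 4·k   |
| 9   | unique-k-mer count of each string                     | 4·N   |
| 10  | `k`, ASCII decimal                                    | 10    |
| 11  | absolute file position of segment 6, ASCII decimal    | 10    |

Total file size: `30 + F·N + 4·P + K·k + 4·k + 4·k + 4·N + 10 + 10`.

Encoding rules:

- All 4-byte integers are **unsigned little-endian**.
- Identifiers and k-mers are latin-1 text; every indexable character
  must fit a single byte so the fixed-width fields hold.
- Posting arrays list, for one k-mer, the ascending 0-based indices of
  strings containing it, **delta-encoded**: the first element verbatim,
  each later element as the gap to its predecessor (gap ≥ 1).  Arrays
  are concatenated with no delimiter — segment 7/8 positions and counts
  locate them.
- Segment 7 positions are absolute byte offsets from file start.
- Strings with zero valid k-mers keep their slot in segments 4 and 9
  (count 0) so indices stay aligned with FASTA record order.
- Segments 10 and 11 sit at the end so a loader can find the tail
  segments by reading the last 20 bytes, then load everything *except*
  segment 5; individual posting arrays are fetched later by seek.

Byte-compatibility with any historical implementation is not claimed;
the format is self-consistent and fully specified here.

## Worked example

Database of two records, `s0 = ACGT` and `s1 = ACGG`, indexed at
`K = 3` with alphabet `ACGT`.  Distinct 3-mers: `ACG → [0, 1]`,
`CGG → [1]`, `CGT → [0]`; unique counts `[2, 2]`; so `F = 2`, `N = 2`,
`k = 3`, `P = 4`, file size `30 + 4 + 16 + 9 + 12 + 12 + 8 + 20 = 111`.

```
00000000  20 20 20 20 20 20 20 20 20 32 20 20 20 20 20 20           2
00000010  20 20 20 33 20 20 20 20 20 20 20 20 20 32 73 30     3         2s0
00000020  73 31 00 00 00 00 01 00 00 00 01 00 00 00 00 00  s1..............
00000030  00 00 41 43 47 43 47 47 43 47 54 22 00 00 00 2a  ..ACGCGGCGT"...*
00000040  00 00 00 2e 00 00 00 02 00 00 00 01 00 00 00 01  ................
00000050  00 00 00 02 00 00 00 02 00 00 00 20 20 20 20 20  ...........
00000060  20 20 20 20 33 20 20 20 20 20 20 20 20 35 30         3        50
```

Reading it back:

- bytes 0–29: `F = 2`, `K = 3`, `N = 2`;
- bytes 30–33 (seg 4): `s0`, `s1`;
- bytes 34–49 (seg 5): posting arrays `[0, 1] → deltas 0,1`,
  `[1] → 1`, `[0] → 0`;
- bytes 50–58 (seg 6, position 50 = `0x32`): `ACG CGG CGT`;
- bytes 59–70 (seg 7): positions `0x22, 0x2a, 0x2e` = 34, 42, 46;
- bytes 71–82 (seg 8): counts 2, 1, 1;
- bytes 83–90 (seg 9): unique counts 2, 2;
- bytes 91–100 (seg 10): `k = 3`;
- bytes 101–110 (seg 11): segment-6 position `50`.
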