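"""Independent brute-force reference implementation used as the oracle.

Deliberately naive and written without reusing any package internals:
dictionary-based complementation, explicit window enumeration, and a
quadratic two-pass scan over fully materialized read lists. Only suitable
for tiny corpora.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def ref_revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def ref_canon(kmer):
    r = ref_revcomp(kmer)
    return kmer if kmer <= r else r


def ref_windows(seq, k):
    """All (position, canonical k-mer) pairs over ACGT-only windows."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out.append((i, ref_canon(w)))
    return out


def ref_is_anchor(seq, trusted, k):
    hits = {pos for pos, km in ref_windows(seq, k) if km in trusted}
    return any(pos + 1 in hits for pos in hits)


def ref_two_pass(seqs, trusted, k, tau):
    """Return (anchor_flags, proportions, retained_flags) per read."""
    flags = [ref_is_anchor(s, trusted, k) for s in seqs]
    anchor_set = set()
    for s, flag in zip(seqs, flags):
        if flag:
            anchor_set.update(km for _, km in ref_windows(s, k))
    props = []
    retained = []
    for s in seqs:
        wins = ref_windows(s, k)
        if wins:
            p = sum(1 for _, km in wins if km in anchor_set) / len(wins)
        else:
            p = 0.0
        props.append(p)
        retained.append(p >= tau)
    return flags, props, retained


def ref_one_pass(seqs, trusted, k):
    return [ref_is_anchor(s, trusted, k) for s in seqs]


def ref_select_trusted(kmers, presence_by_label):
    """Truth-table evaluation of the trusted-set formula, row by row.

    ``presence_by_label`` maps each k-mer to a list of (label, present)
    pairs, one per sample column.
    """
    out = set()
    for km in kmers:
        cols = presence_by_label[km]
        in_aoral = any(p for lb, p in cols if lb == "aOral")
        in_moral = any(p for lb, p in cols if lb == "mOral")
        in_skin = any(p for lb, p in cols if lb == "Skin")
        in_soil = any(p for lb, p in cols if lb == "SedimentSoil")
        if (in_aoral or in_moral) and not (in_skin or in_soil):
            out.add(km)
    return out
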