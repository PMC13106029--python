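"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive the same contracts by different means: the mapper
oracle scans every contig with ``str.find`` on both strands; the duplex oracle
enumerates alignments by literal string surgery (deleting the bulged site base
or inserting a gap placeholder) and scores the resulting ungapped pairing.
"""

from ckrna.seqio import AnnotatedGenome, revcomp

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def naive_loci(genome: AnnotatedGenome, query: str) -> list[tuple[str, int, int, str]]:
    """All perfect full-length occurrences on both strands, by full scan."""
    out = set()
    n = len(query)
    for contig in genome.contigs:
        seq = contig.sequence
        for target, strand in ((query, "+"), (revcomp(query), "-")):
            start = 0
            while True:
                i = seq.find(target, start)
                if i < 0:
                    break
                out.add((contig.id, i, i + n, strand))
                start = i + 1
    return sorted(out)


def _weight(i: int) -> float:
    return 2.0 if 2 <= i <= 12 else 1.0


def _pair_penalty(s: str, t: str) -> float:
    if t == _COMP[s]:
        return 0.0
    if (s, t) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def _score_flat(srna: str, site_n: str) -> float:
    """Ungapped antiparallel score; '-' in the site marks an sRNA gap."""
    n = len(srna)
    total = 0.0
    for i in range(1, n + 1):
        t = site_n[n - i]
        if t == "-":
            total += 2.0 * _weight(i)
        else:
            total += _pair_penalty(srna[i - 1], t) * _weight(i)
    return total


def oracle_best_score(srna: str, site: str) -> float:
    """Exhaustive minimum score over all <=1-gap alignments."""
    n, m = len(srna), len(site)
    scores = []
    if m == n:
        scores.append(_score_flat(srna, site))
    elif m == n + 1:
        for b in range(1, n):  # delete one internal site base (the bulge)
            j = n - b  # bulge sits between sRNA positions j and j+1
            bulge_pen = 2.0 * (2.0 if 2 <= j + 1 <= 12 else 1.0)
            scores.append(_score_flat(srna, site[:b] + site[b + 1 :]) + bulge_pen)
    elif m == n - 1:
        for c in range(n):  # insert a gap placeholder into the site
            scores.append(_score_flat(srna, site[:c] + "-" + site[c:]))
    else:
        raise ValueError("length difference > 1")
    return min(scores)
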