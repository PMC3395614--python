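"""Independent brute-force oracles used by the test suites.

These deliberately avoid the package's own code paths: translation goes
through Biopython, pathway enumeration is explicit over permutations.
"""

import itertools

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_count(codon: str) -> float:
    """Synonymous sites of one codon, counted directly from the genetic code."""
    total = 0.0
    for pos in range(3):
        syn = considered = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOPS:
                continue
            considered += 1
            syn += aa(mut) == aa(codon)
        total += syn / considered if considered else 0.0
    return total


def oracle_diff_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) steps over stop-free orderings.

    If every ordering crosses a stop codon, fall back to averaging over all
    orderings, counting only the steps between sense codons.
    """
    positions = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(positions):
        path = [ca]
        for pos in order:
            path.append(path[-1][:pos] + cb[pos] + path[-1][pos + 1 :])
        if any(c in STOPS for c in path[1:]):
            continue
        sd = sum(aa(x) == aa(y) for x, y in zip(path, path[1:]))
        results.append((sd, len(positions) - sd))
    if not results:
        for order in itertools.permutations(positions):
            path = [ca]
            sd = steps = 0
            for pos in order:
                nxt = path[-1][:pos] + cb[pos] + path[-1][pos + 1 :]
                if path[-1] not in STOPS and nxt not in STOPS:
                    steps += 1
                    sd += aa(nxt) == aa(path[-1])
                path.append(nxt)
            results.append((sd, steps - sd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd
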