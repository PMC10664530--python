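"""Independent brute-force reference computations for the usage indices.

Everything here works directly from a codon string list and its own tables,
deliberately sharing no code with the package implementation: no pooling of
family logic, no count-table container, explicit loops throughout.
"""

from collections import Counter
from itertools import permutations

# standard genetic code, written out by hand
ORACLE_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def _families():
    fams = {}
    for codon, aa in ORACLE_CODE.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: sorted(cs) for aa, cs in fams.items() if len(cs) > 1}


def split_codons(nt):
    return [nt[i:i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]


def oracle_rscu(codons):
    counts = Counter(codons)
    out = {}
    for aa, members in _families().items():
        total = sum(counts[c] for c in members)
        if total == 0:
            continue
        for c in members:
            out[c] = counts[c] * len(members) / total
    return out


def oracle_enc(codons):
    counts = Counter(codons)
    f_by_class = {2: [], 3: [], 4: [], 6: []}
    for aa, members in _families().items():
        n = sum(counts[c] for c in members)
        if n < 2:
            continue
        s = sum((counts[c] / n) ** 2 for c in members)
        f = (n * s - 1) / (n - 1)
        f_by_class[len(members)].append(f)
    fbar = {}
    for k, fs in f_by_class.items():
        mean = sum(fs) / len(fs) if fs else 0.0
        fbar[k] = mean if mean > 0 else None
    defined = sorted(k for k in fbar if fbar[k] is not None)

    def nearest(k):
        best = min(abs(j - k) for j in defined)
        picks = [fbar[j] for j in defined if abs(j - k) == best]
        return sum(picks) / len(picks)

    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        n3 = (1 / fbar[2] + 1 / fbar[4]) / 2
    else:
        n3 = 1 / (fbar[3] if fbar[3] is not None else nearest(3))
    f2 = fbar[2] if fbar[2] is not None else nearest(2)
    f4 = fbar[4] if fbar[4] is not None else nearest(4)
    f6 = fbar[6] if fbar[6] is not None else nearest(6)
    value = 2 + 9 / f2 + n3 + 5 / f4 + 3 / f6
    return min(value, 61.0)


def oracle_cai(codons, w):
    product = 1.0
    n = 0
    fams = _families()
    synonymous = {c for members in fams.values() for c in members}
    for c in codons:
        if c in synonymous:
            product *= w[c]
            n += 1
    return product ** (1.0 / n)


def oracle_optimal(w):
    out = {}
    for aa, members in _families().items():
        out[aa] = max(members, key=lambda c: (w[c], c))
    return out


def oracle_cbi(codons, w):
    counts = Counter(codons)
    optimal = oracle_optimal(w)
    n_opt = n_tot = 0
    n_ran = 0.0
    for aa, members in _families().items():
        total = sum(counts[c] for c in members)
        if total == 0:
            continue
        n_tot += total
        n_opt += counts[optimal[aa]]
        n_ran += total / len(members)
    return (n_opt - n_ran) / (n_tot - n_ran)


def oracle_fop(codons, w):
    counts = Counter(codons)
    optimal = oracle_optimal(w)
    n_opt = n_tot = 0
    for aa, members in _families().items():
        total = sum(counts[c] for c in members)
        n_tot += total
        n_opt += counts[optimal[aa]]
    return n_opt / n_tot


def oracle_gravy(codons):
    aas = [ORACLE_CODE[c] for c in codons]
    return sum(KD_HYDROPATHY[a] for a in aas) / len(aas)


def oracle_aromo(codons):
    aas = [ORACLE_CODE[c] for c in codons]
    return sum(a in "FYW" for a in aas) / len(aas)


def oracle_lengths(codons):
    fams = _families()
    synonymous = {c for members in fams.values() for c in members}
    l_aa = sum(c in ORACLE_CODE for c in codons)
    l_sym = sum(c in synonymous for c in codons)
    return l_sym, l_aa


def oracle_composition(codons):
    fams = _families()
    synonymous = {c for members in fams.values() for c in members}
    kept = [c for c in codons if c in synonymous]
    total = len(kept)
    pct = {}
    for base in "ATGC":
        pct[base + "3"] = 100.0 * sum(c[2] == base for c in kept) / total
    gc = {}
    for pos in range(3):
        gc[pos] = 100.0 * sum(c[pos] in "GC" for c in kept) / total
    return {
        "A3": pct["A3"], "T3": pct["T3"], "G3": pct["G3"], "C3": pct["C3"],
        "GC1": gc[0], "GC2": gc[1], "GC3": gc[2],
        "GC12": (gc[0] + gc[1]) / 2,
        "GCs": (gc[0] + gc[1] + gc[2]) / 3,
        "ATs": 100 - (gc[0] + gc[1] + gc[2]) / 3,
    }


def oracle_spearman(x, y):
    """Exact Spearman rho and two-sided permutation p for tiny samples."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    def pearson(a, b):
        n = len(a)
        ma = sum(a) / n
        mb = sum(b) / n
        num = sum((p - ma) * (q - mb) for p, q in zip(a, b))
        da = sum((p - ma) ** 2 for p in a) ** 0.5
        db = sum((q - mb) ** 2 for q in b) ** 0.5
        return num / (da * db)

    rx, ry = ranks(x), ranks(y)
    rho = pearson(rx, ry)
    count = total = 0
    for perm in permutations(rx):
        total += 1
        if abs(pearson(list(perm), ry)) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total
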