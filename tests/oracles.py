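"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorised algorithms in the package: the SSR
oracle tests every (start, period) candidate by direct string comparison,
and the genotype oracle tallies alleles with plain dictionaries.
"""

from collections import Counter


def brute_force_ssrs(seq, chrom, min_len=10, min_repeat=3):
    """All maximal perfect repeats by exhaustive per-start unit extension."""
    from math import ceil

    def primitive(unit):
        n = len(unit)
        return not any(n % d == 0 and unit == unit[:d] * (n // d)
                       for d in range(1, n))

    s = seq.upper()
    n = len(s)
    found = []
    for period in (2, 3, 4, 5, 6):
        min_reps = max(min_repeat, ceil(min_len / period))
        for start in range(0, n - period):
            unit = s[start:start + period]
            if s[start + period:start + 2 * period] != unit:
                continue
            if any(c not in "ACGT" for c in unit):
                continue
            # leftmost anchor: the per-base match chain must break at start-1
            if start > 0 and s[start - 1] in "ACGT" and start - 1 + period < n \
                    and s[start - 1] == s[start - 1 + period]:
                continue
            if not primitive(unit):
                continue
            reps = 1
            while s[start + reps * period:start + (reps + 1) * period] == unit:
                reps += 1
            if reps >= min_reps and reps * period >= min_len:
                found.append((chrom, start, start + reps * period, unit, reps))
    found.sort(key=lambda t: (t[1], t[2], len(t[3])))
    return found


def tally_locus(rows):
    """Naive per-chromosome allele tally for one locus.

    ``rows`` is an iterable of (allele_a, allele_b) pairs; returns a dict of
    frequency, maf, het, pic computed with plain loops.
    """
    counts = Counter()
    n_het = 0
    rows = list(rows)
    for a, b in rows:
        counts[a] += 1
        counts[b] += 1
        if a != b:
            n_het += 1
    total = sum(counts.values())
    freqs = {allele: c / total for allele, c in counts.items()}
    ordered = sorted(freqs.values(), reverse=True)
    return {
        "freqs": freqs,
        "n_alleles": len(freqs),
        "maf": ordered[1] if len(ordered) > 1 else 0.0,
        "het_obs": n_het / len(rows),
        "pic": 1.0 - sum(p * p for p in freqs.values()),
    }
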