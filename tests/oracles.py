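"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own indexing/vectorization paths:
contexts are derived by literal string surgery on the reverse complement,
metrics by explicit loops, and profiles by per-base iteration.
"""

from Bio.Seq import Seq

H = set("ACT")


def brute_force_context(seq: str, pos: int, strand: str):
    """Classify by slicing the literal strand sequence."""
    if strand == "+":
        oriented = seq
        j = pos
    else:
        oriented = str(Seq(seq).reverse_complement())
        j = len(seq) - 1 - pos
    if oriented[j] != "C":
        return "not-C"
    downstream = oriented[j + 1:j + 3]
    if len(downstream) >= 1 and downstream[0] == "G":
        return "CG"
    if len(downstream) < 2 or "N" in downstream:
        return None
    if downstream[0] in H and downstream[1] == "G":
        return "CHG"
    if downstream[0] in H and downstream[1] in H:
        return "CHH"
    return None


def brute_force_metrics(labels, calls):
    tp = fp = fn = tn = 0
    for y, c in zip(labels, calls):
        if y == 1 and c == 1:
            tp += 1
        elif y == 0 and c == 1:
            fp += 1
        elif y == 1 and c == 0:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_bin_of_base(g: int, start: int, end: int, strand: str,
                            flank: int = 2000, flank_bin: int = 400):
    """1-based bin index (1..15) of genomic base g relative to one gene, or
    None when outside the profiled span.  Per-base mirror of the interval
    scheme: remainder of the body division goes to the 3'-most body bin."""
    gl = end - start
    base = gl // 5
    if strand == "+":
        if start - flank <= g < start:
            u = start - g  # 1..flank
            return (flank - u) // flank_bin + 1
        if start <= g < end:
            d = g - start
            return 6 + min(d // base, 4)
        if end <= g < end + flank:
            return 11 + (g - end) // flank_bin
    else:
        if end <= g < end + flank:
            u = g - end + 1
            return (flank - u) // flank_bin + 1
        if start <= g < end:
            d = end - 1 - g
            return 6 + min(d // base, 4)
        if start - flank <= g < start:
            return 11 + (start - 1 - g) // flank_bin
    return None


def brute_force_gene_profile(calls, genes, context, orientation):
    """Per-base recomputation of the 15-bin weighted metaprofile."""
    from amps.methylome import METHYLATED, UNKNOWN

    called = {}
    for rec in calls:
        if rec.context == context and rec.status != UNKNOWN:
            called[(rec.chrom, rec.pos, rec.strand)] = rec.status == METHYLATED

    num = [0.0] * 15
    den = [0.0] * 15
    for gene in genes:
        chrom_len = len(calls.genomes[gene.chrom])
        strand = gene.strand if orientation == "nontemplate" else \
            ("-" if gene.strand == "+" else "+")
        meth = [0] * 15
        ncalled = [0] * 15
        length = [0] * 15
        for g in range(max(gene.start - 2000, -2000),
                       min(gene.end + 2000, chrom_len + 2000)):
            r = brute_force_bin_of_base(g, gene.start, gene.end, gene.strand)
            if r is None or not 0 <= g < chrom_len:
                continue
            length[r - 1] += 1
            key = (gene.chrom, g, strand)
            if key in called:
                ncalled[r - 1] += 1
                meth[r - 1] += called[key]
        for r in range(15):
            if ncalled[r] > 0:
                num[r] += (meth[r] / ncalled[r]) * length[r]
                den[r] += length[r]
    return [num[r] / den[r] if den[r] > 0 else None for r in range(15)]
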