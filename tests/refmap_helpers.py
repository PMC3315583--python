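from estforge.refmap import LocusAssignment


def make_assignment(qid, chrom, start, end, strand="+"):
    return LocusAssignment(query_id=qid, chrom=chrom, tstart=start, tend=end,
                           strand=strand, score=float(end - start), identity=1.0)
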