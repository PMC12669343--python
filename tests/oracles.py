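"""Independent brute-force oracles shared across test modules."""


def brute_force_threshold(correct: list[bool], intensities: list[float]) -> float:
    """Scan a trial log, enumerate maximal incorrect runs, weight each by
    k(k+1)/2 and average their mean intensities."""
    from stepcal.step import EstimationError

    runs = []
    current = []
    for c, x in zip(correct, intensities):
        if c:
            if current:
                runs.append(current)
            current = []
        else:
            current.append(x)
    if current:
        runs.append(current)
    if not runs:
        raise EstimationError("no incorrect trials")
    num = den = 0.0
    for r in runs:
        k = len(r)
        w = k * (k + 1) / 2
        num += w * (sum(r) / k)
        den += w
    return num / den
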