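"""Independent brute-force implementations of the five score equations.

Plain-python loop versions used as oracles; deliberately kept free of
the package's vectorised code paths.
"""

import math


def oracle_es(antigenic, non_antigenic, L=100):
    """Direct evaluation of the four ES-CCF equations."""

    def rank_of(c):
        edge = math.ceil(round(c * L, 9))
        edge = min(max(edge, 1), L)
        return L - edge + 1

    def masses(ccfs):
        m = [0] * (L + 1)
        for c in ccfs:
            if c > 0:
                m[rank_of(c)] += 1
        weighted = [m[r] * (abs(L / 2 - r) + 1) for r in range(1, L + 1)]
        total = sum(weighted)
        return [w / total for w in weighted]

    a_n = masses(antigenic)
    a_m = masses(non_antigenic)
    f_n = f_m = 0.0
    d_max = d_min = 0.0
    for r in range(L):
        f_n += a_n[r]
        f_m += a_m[r]
        d = f_n - f_m
        d_max = max(d_max, d)
        d_min = min(d_min, d)
    return max(0.0, d_max) - abs(min(0.0, d_min))


def oracle_oe_ref_sample(records, nbar, bbar):
    """records: list of (context_index, consequence, is_neo)."""
    n_obs = s_obs = b_obs = 0
    n_pred = b_pred = 0.0
    for cid, cons, neo in records:
        if cons == "synonymous":
            s_obs += 1
            if not (math.isnan(nbar[cid]) or math.isnan(bbar[cid])):
                n_pred += nbar[cid]
                b_pred += bbar[cid] * nbar[cid]
        elif cons == "nonsynonymous":
            n_obs += 1
            if neo:
                b_obs += 1
    if n_obs < 1 or s_obs < 1 or n_pred <= 0 or b_pred <= 0:
        return float("nan")
    return (b_obs / n_obs) / (b_pred / n_pred)


def oracle_oe_codon(records, psyn, b_coding):
    n_obs = s_obs = b_obs = 0
    n_pred = 0.0
    n_coding = 0
    for cid, cons, neo in records:
        if cons not in ("synonymous", "nonsynonymous"):
            continue
        n_coding += 1
        if not math.isnan(psyn[cid]):
            n_pred += 1.0 - psyn[cid]
        if cons == "synonymous":
            s_obs += 1
        else:
            n_obs += 1
            if neo:
                b_obs += 1
    b_pred = b_coding * n_coding
    if n_obs < 1 or s_obs < 1 or n_pred <= 0 or b_pred <= 0:
        return float("nan")
    return (b_obs / n_obs) / (b_pred / n_pred)


def oracle_hbmr(mut_records, sub_records, pt):
    """Normalized HBMR from plain tallies.

    mut_records: (is_binding, is_synonymous) per observed mutation;
    sub_records: (is_binding, is_synonymous, class96) per possible
    substitution of the region set; pt: 96 class probabilities.
    """
    nb = sb = nn = sn = 0
    for binding, syn in mut_records:
        if binding and not syn:
            nb += 1
        elif binding and syn:
            sb += 1
        elif not binding and not syn:
            nn += 1
        else:
            sn += 1
    if sb < 1 or sn < 1 or nn < 1:
        return float("nan")
    obs = (nb / sb) / (nn / sn)
    enb = [0.0] * 96
    esb = [0.0] * 96
    enn = [0.0] * 96
    esn = [0.0] * 96
    for binding, syn, t in sub_records:
        if binding and not syn:
            enb[t] += 1
        elif binding and syn:
            esb[t] += 1
        elif not binding and not syn:
            enn[t] += 1
        else:
            esn[t] += 1
    num = sum(enb[t] * pt[t] for t in range(96)) / sum(esb[t] * pt[t] for t in range(96))
    den = sum(enn[t] * pt[t] for t in range(96)) / sum(esn[t] * pt[t] for t in range(96))
    exp = num / den
    return obs / exp


def oracle_immune_dnds(mut_records, sub_records, weights):
    """mut_records: (is_on, is_synonymous); sub_records: (is_on,
    is_synonymous, context192); weights: 192-vector summing to 1."""
    n_on = s_on = n_off = s_off = 0
    for on, syn in mut_records:
        if on and syn:
            s_on += 1
        elif on:
            n_on += 1
        elif syn:
            s_off += 1
        else:
            n_off += 1
    nsite_on = ssite_on = nsite_off = ssite_off = 0.0
    for on, syn, cid in sub_records:
        w = weights[cid]
        if on and syn:
            ssite_on += w
        elif on:
            nsite_on += w
        elif syn:
            ssite_off += w
        else:
            nsite_off += w
    if s_on < 1 or s_off < 1 or min(nsite_on, ssite_on, nsite_off, ssite_off) <= 0:
        return float("nan")
    dnds_on = (n_on / nsite_on) / (s_on / ssite_on)
    dnds_off = (n_off / nsite_off) / (s_off / ssite_off)
    return dnds_on / dnds_off
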