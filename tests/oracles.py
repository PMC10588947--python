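"""Independent straight-line oracles used by the test suite.

Everything here is deliberately scalar, unvectorized Python with its own
arithmetic — literal transcriptions of the update and decision rules plus
textbook closed forms — so that agreement with the package is meaningful.
"""

import math

import scipy.stats


def straight_line_trial_probs(model, params, trials):
    """Probability of each observed choice for one block of trials.

    ``trials`` is an iterable of dicts with keys offer_a, offer_b, choice,
    reward01; ``params`` is a dict of natural-scale parameter values.
    """
    n_arms = 1 + max(max(t["offer_a"], t["offer_b"]) for t in trials)
    q = [0.5] * n_arms
    q_sel = [0.5] * n_arms
    q_rej = [0.5] * n_arms
    beta = params["beta"]
    probs = []
    for t in trials:
        a, b = t["offer_a"], t["offer_b"]
        c = t["choice"]
        u = b if c == a else a
        r = t["reward01"]
        if model == "select_reject":
            w = params["omega"]
            v_c = w * q_sel[c] + (1 - w) * q_rej[u]
            v_u = w * q_sel[u] + (1 - w) * q_rej[c]
        else:
            v_c, v_u = q[c], q[u]
        p = math.exp(beta * v_c) / (math.exp(beta * v_c) + math.exp(beta * v_u))
        probs.append(p)

        if model == "baseline":
            delta = r - q[c]
            q[c] = q[c] + params["alpha_chosen"] * delta
        elif model == "double_two_pe":
            delta = r - q[c]
            q[c] = q[c] + params["alpha_chosen"] * delta
            delta_u = (1 - r) - q[u]
            q[u] = q[u] + params["alpha_unchosen"] * delta_u
        elif model == "double_one_pe":
            delta = r - q[c]
            q[c] = q[c] + params["alpha_chosen"] * delta
            q[u] = q[u] + params["alpha_unchosen"] * (-delta)
        elif model == "select_reject":
            delta = r - q_sel[c]
            q_sel[c] = q_sel[c] + params["alpha_chosen"] * delta
            delta_u = r - q_rej[u]
            q_rej[u] = q_rej[u] + params["alpha_chosen"] * delta_u
        else:
            raise ValueError(model)
        for arr in (q, q_sel, q_rej):
            for i in range(n_arms):
                if arr[i] > 1.0:
                    arr[i] = 1.0
                if arr[i] < 0.0:
                    arr[i] = 0.0
    return probs


def straight_line_loglik(model, params, trials):
    return sum(math.log(p) for p in straight_line_trial_probs(model, params, trials))


def brute_force_elpd(model, per_draw_params, trials):
    """log of the across-draw mean probability, per trial, by plain loops."""
    n = len(trials)
    sums = [0.0] * n
    for params in per_draw_params:
        probs = straight_line_trial_probs(model, params, trials)
        for i in range(n):
            sums[i] += probs[i]
    return [math.log(s / len(per_draw_params)) for s in sums]


def hierarchical_prior_logpdf(loc, log_scale, z, location_sd=2.0, scale_gamma=2.0):
    """Prior density of the non-centered hierarchy, via scipy distributions.

    Scales enter on the log scale, so the half-Cauchy density picks up a
    Jacobian term of ``+ log(scale)`` per scale parameter.
    """
    lp = 0.0
    for v in loc:
        lp += scipy.stats.norm(0.0, location_sd).logpdf(v)
    for ls in log_scale:
        s = math.exp(ls)
        lp += scipy.stats.halfcauchy(scale=scale_gamma).logpdf(s) + ls
    for row in z:
        for v in row:
            lp += scipy.stats.norm(0.0, 1.0).logpdf(v)
    return lp


def normal_known_variance_posterior(data, sigma, prior_mean, prior_sd):
    """Conjugate posterior (mean, sd) of a Normal mean with known variance."""
    n = len(data)
    prec = 1.0 / prior_sd**2 + n / sigma**2
    mean = (prior_mean / prior_sd**2 + sum(data) / sigma**2) / prec
    return mean, math.sqrt(1.0 / prec)
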