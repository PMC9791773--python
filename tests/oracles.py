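"""Independent brute-force oracles for the scoring rules.

These read the verbal scoring rules directly against hand-transcribed
cutoff tables, deliberately bypassing the package's standard objects and
dispatch, so they can arbitrate the implementation on dense grids.
"""

# (category, max score, young cutoffs, old cutoffs); moderation cutoffs are
# (lower, upper), adequacy a single recommended density, limitation a limit.
TABLE_CUTOFFS = {
    "vegetables": ("adequacy", 10, 167, 179),
    "fruits": ("adequacy", 10, 83, 107),
    "dairy": ("adequacy", 10, 417, 250),
    "soybeans": ("adequacy", 10, 4, 11),
    "aquatic_products": ("adequacy", 10, 12.5, 14),
    "cereals": ("moderation", 10, (71, 100), (71, 125)),
    "eggs": ("moderation", 10, (17, 25), (18, 21)),
    "red_meat_poultry": ("moderation", 10, (12.5, 25), (18, 33)),
    "vitamin_a": ("moderation", 2.5, (258, 700), (257, 750)),
    "iron": ("moderation", 2.5, (7.5, 25), (7.1, 25)),
    "snacks": ("limitation", 5, 100, 100),
}

# Minimum-score (zero) criteria as printed, for cross-checking the
# moderation zero rule independently of the 2 x upper relation.
TABLE_ZERO_ABOVE = {
    "cereals": (200, 250),
    "eggs": (50, 42),
    "red_meat_poultry": (50, 66),
    "vitamin_a": (1400, 1500),
    "iron": (50, 50),
}


def oracle_adequacy(density, recommended, max_score):
    """Full marks at/above the recommendation, proportional credit below."""
    if density >= recommended:
        return float(max_score)
    return density / recommended * max_score


def oracle_moderation(density, lower, upper, max_score):
    """Full marks in [lower, upper]; zero at 0 intake or above twice the
    upper bound; otherwise (1 - |1 - density/bound|) x max with the bound
    nearest to the density."""
    if density == 0 or density > 2 * upper:
        return 0.0
    if lower <= density <= upper:
        return float(max_score)
    bound = lower if density < lower else upper
    return (1 - abs(1 - density / bound)) * max_score


def oracle_limitation(density, limit, max_score):
    """Full marks at zero intake, linear decay to zero at the limit."""
    if density >= limit:
        return 0.0
    return (1 - density / limit) * max_score


def oracle_score(component_id, group_label, density):
    """Score one density through the verbal rules; group is 'young'/'old'."""
    category, max_score, young, old = TABLE_CUTOFFS[component_id]
    cut = young if group_label == "young" else old
    if category == "adequacy":
        return oracle_adequacy(density, cut, max_score)
    if category == "moderation":
        return oracle_moderation(density, cut[0], cut[1], max_score)
    return oracle_limitation(density, cut, max_score)
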