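"""Published summary values of the empirical study system.

These are the printed per-group summaries of the 90-individual,
1,217-bp concatenated cytb + control-region mtDNA dataset (five regional
population groups of a Cuban cave-restricted fish).  They serve two
purposes: as *inputs* for statistics that are functions of printed
summaries alone (Tajima's D from (n, S, mean pairwise differences);
Fu's Fs from (n, mean k, number of haplotypes); coalescent p-values for
a printed statistic), and as *reference values* that recomputations are
compared against.  The underlying per-sequence alignment and
per-locality haplotype frequency matrix were published only as
supplementary material and are not redistributed here; analyses that
need them accept a user-supplied haplotype table instead.
"""

L = 1217  # concatenated alignment length (bp)

# per-group N, S, NH, h (+sd), pi (+sd)
TABLE_DIVERSITY = {
    "Guanahacabibes": {"n": 6, "S": 2, "NH": 2, "h": 0.600, "h_sd": 0.129,
                       "pi": 0.0010, "pi_sd": 0.0008},
    "Cayuco": {"n": 17, "S": 18, "NH": 11, "h": 0.882, "h_sd": 0.072,
               "pi": 0.0021, "pi_sd": 0.0013},
    "Havana": {"n": 29, "S": 42, "NH": 16, "h": 0.924, "h_sd": 0.030,
               "pi": 0.0065, "pi_sd": 0.0034},
    "Bolondron": {"n": 23, "S": 12, "NH": 11, "h": 0.909, "h_sd": 0.034,
                  "pi": 0.0023, "pi_sd": 0.0014},
    "Agramonte": {"n": 15, "S": 15, "NH": 9, "h": 0.924, "h_sd": 0.044,
                  "pi": 0.0035, "pi_sd": 0.0021},
    "overall": {"n": 90, "S": 81, "NH": 49, "h": 0.979, "h_sd": 0.005,
                "pi": 0.0100, "pi_sd": 0.0050},
}

# demographic table: tau, theta0, SSD, R2, Fs per group
TABLE_DEMOGRAPHY = {
    "Guanahacabibes": {"n": 6, "tau": 2.42, "theta0": 0.00, "ssd": 0.233,
                       "r2": 0.300, "fs": 1.938},
    "Cayuco": {"n": 17, "tau": 1.72, "theta0": 0.00, "ssd": 0.009,
               "r2": 0.083, "fs": -5.736},
    "Havana": {"n": 29, "tau": 5.89, "theta0": 2.36, "ssd": 0.021,
               "r2": 0.085, "fs": -2.072},
    "Bolondron": {"n": 23, "tau": 3.12, "theta0": 0.10, "ssd": 0.003,
                  "r2": 0.097, "fs": -3.540},
    "Agramonte": {"n": 15, "tau": 5.44, "theta0": 0.00, "ssd": 0.005,
                  "r2": 0.129, "fs": -1.572},
}

TAJIMA_D_OVERALL = -0.841
F_CT_FIVE_GROUPS = 0.656
SAMOVA_K2_FCT = 0.514
MIN_STEPS_CENTRE_EAST = 10       # network separation, central vs eastern groups
SCENARIO3_POSTERIOR = 0.82       # east-to-west stepping stone, mean of 3 runs
SCENARIO1_POSTERIOR = 0.0
FST_RANGE = (0.46, 0.91)

# the smallest group is fully determined by its printed summaries:
# two haplotypes at counts 3/3 differing at the group's S = 2 sites
GUANAHACABIBES_COUNTS = (3, 3)
GUANAHACABIBES_DIFFS = 2


def k_mean_from_pi(pi: float, length: int = L) -> float:
    """Mean pairwise differences implied by a printed nucleotide diversity."""
    return pi * length
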