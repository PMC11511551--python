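"""Bundled reference data.

The 28-marker diversity table for the *Dendrocalamus brandisii* panel
(one new cultivar plus eleven geographic provenances, genotyped with 28
polymorphic genomic SSR markers) ships with the package as published
input data: per-marker observed (Na) and effective (Ne) allele numbers,
Shannon's index (I), observed and expected heterozygosity, and PIC.
It is used to exercise and validate panel-level summaries.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["bamboo_marker_panel"]

_BAMBOO_PANEL_TSV = """\
marker\tNa\tNe\tI\tHo\tHe\tPIC
SSR2\t3\t2.0000\t0.8676\t0.4783\t0.5217\t0.4491
SSR84\t4\t3.4286\t1.3086\t0.2609\t0.7391\t0.6589
SSR52\t2\t1.9459\t0.6792\t0.4928\t0.5072\t0.3680
SSR522\t5\t4.0000\t1.4735\t0.2174\t0.7826\t0.7078
SSR18\t2\t1.3846\t0.4506\t0.7101\t0.2899\t0.2392
SSR394\t6\t2.3415\t1.2109\t0.4022\t0.5978\t0.5436
SSR751\t2\t1.9862\t0.6897\t0.4819\t0.5181\t0.3733
SSR243\t3\t2.3415\t0.9222\t0.4022\t0.5978\t0.4788
SSR571\t4\t2.5487\t1.0618\t0.3659\t0.6341\t0.5280
SSR122\t2\t1.3846\t0.4506\t0.7101\t0.2899\t0.2392
SSR599\t4\t2.7429\t1.1219\t0.3370\t0.6630\t0.5630
SSR41\t2\t1.1803\t0.2868\t0.8406\t0.1594\t0.1411
SSR554\t3\t2.1818\t0.8877\t0.4348\t0.5652\t0.4598
SSR49\t2\t1.1803\t0.2868\t0.8406\t0.1594\t0.1411
SSR711\t2\t1.1803\t0.2868\t0.8406\t0.1594\t0.1411
SSR100\t3\t1.4118\t0.5661\t0.6957\t0.3043\t0.2723
SSR237\t2\t1.9862\t0.6897\t0.4819\t0.5181\t0.3733
SSR417\t2\t1.1803\t0.2868\t0.8406\t0.1594\t0.1411
SSR236\t5\t2.7961\t1.2015\t0.3297\t0.6703\t0.5748
SSR527\t4\t2.3415\t0.9762\t0.4022\t0.5978\t0.4832
SSR39\t3\t2.3226\t0.9184\t0.4058\t0.5942\t0.4768
SSR497\t2\t1.9459\t0.6792\t0.4928\t0.5072\t0.3680
SSR624\t2\t1.9459\t0.6792\t0.4928\t0.5072\t0.3680
SSR102\t2\t1.3846\t0.4506\t0.7101\t0.2899\t0.2392
SSR205\t2\t1.9459\t0.6792\t0.4928\t0.5072\t0.3680
SSR602\t3\t2.3415\t0.9222\t0.4022\t0.5978\t0.4788
SSR171\t2\t1.9459\t0.6792\t0.4928\t0.5072\t0.3680
SSR570\t3\t1.4118\t0.5661\t0.6957\t0.3043\t0.2723
"""


def bamboo_marker_panel() -> pd.DataFrame:
    """Published per-marker diversity indices for the 28-SSR bamboo panel.

    Columns: marker, Na, Ne, I, Ho, He, PIC (values as printed, 4
    decimals).  Note the Ho column of the source equals ``1 - He`` row by
    row — it is the mean homozygosity reported by legacy software, not
    the observed heterozygosity computed from genotypes.
    """
    return pd.read_csv(io.StringIO(_BAMBOO_PANEL_TSV), sep="\t")
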