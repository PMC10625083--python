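{
  "platform": "twitter",
  "n_total": 1978,
  "note": "Category shares of depressive-discourse tweets from a prior qualitative content analysis (n=1978). Only the printed per-category shares are stored; no raw tweets were used.",
  "cells": {
    "apathy_sadness": {
      "percent": 7.53,
      "count": 149,
      "provenance": "printed share, 149/1978 tweets"
    },
    "dysfunctional_thoughts": {
      "percent": 25.17,
      "count": 498,
      "provenance": "printed share, 498/1978 tweets"
    },
    "social_struggles": {
      "percent": 21.89,
      "count": 433,
      "provenance": "printed share, 433/1978 tweets"
    },
    "hiding_behind_mask": {
      "percent": 11.93,
      "count": 256,
      "provenance": "printed share 11.93% alongside printed fraction 256/1978; the fraction evaluates to 12.94%, an inconsistency in the source print. The printed percent is stored verbatim and this cell is flagged.",
      "discrepancy": true
    }
  }
}
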