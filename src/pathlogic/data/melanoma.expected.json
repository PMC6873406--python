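{
 "healthy_output": [
  0,
  0,
  0,
  1
 ],
 "healthy_score": -1,
 "mutation_labels": [
  "BRAF",
  "RAF",
  "NRAS",
  "RAS",
  "AKT",
  "PI3K",
  "MEK",
  "CDK4/6"
 ],
 "s_without": [
  -1,
  -1,
  0,
  0,
  0,
  0,
  -1,
  0
 ],
 "drugs": {
  "Everolimus": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    0
   ],
   "cumulative": -7
  },
  "BKM120": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    0,
    -1,
    -1,
    0
   ],
   "cumulative": -6
  },
  "Ribociclib": {
   "cells": [
    -1,
    -1,
    0,
    0,
    0,
    0,
    -1,
    -1
   ],
   "cumulative": -4
  },
  "Trametinib": {
   "cells": [
    -1,
    -1,
    0,
    0,
    0,
    0,
    -1,
    0
   ],
   "cumulative": -3
  },
  "Dabrafenib": {
   "cells": [
    -1,
    -1,
    0,
    0,
    0,
    0,
    -1,
    0
   ],
   "cumulative": -3
  },
  "Omacetaxine": {
   "cells": [
    -1,
    -1,
    0,
    0,
    0,
    0,
    -1,
    0
   ],
   "cumulative": -3
  }
 },
 "drug_combos": {
  "Everolimus/Ribociclib": {
   "interventions": [
    "Everolimus",
    "Ribociclib"
   ],
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "Everolimus/BKM120": {
   "interventions": [
    "BKM120",
    "Everolimus"
   ],
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    0
   ],
   "cumulative": -7
  }
 },
 "mirnas": {
  "mir-124": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "mir-155": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "mir-497": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "mir-16": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "let-7b": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "mir-302a": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1
   ],
   "cumulative": -8
  },
  "let-7a": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    0,
    -1,
    -1,
    -1
   ],
   "cumulative": -7
  },
  "mir-143": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    0
   ],
   "cumulative": -7
  },
  "mir-7": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    -1,
    0
   ],
   "cumulative": -7
  },
  "mir-145": {
   "cells": [
    -1,
    -1,
    -1,
    0,
    0,
    0,
    -1,
    -1
   ],
   "cumulative": -5
  },
  "mir-429": {
   "cells": [
    -1,
    -1,
    -1,
    -1,
    0,
    0,
    -1,
    -1
   ],
   "cumulative": -6
  }
 },
 "mirna_combos": {},
 "printed_deviations": [
  {
   "where": "mirnas:mir-143:NRAS",
   "printed": 0,
   "computed": -1,
   "note": "mir-143 targets AKT, and blocking AKT restores BAD under every upstream fault \u2014 as the published mir-7 and let-7b NRAS cells show; notably the published Ranking -7 matches the corrected row sum, not the printed cells (which sum to -6)"
  },
  {
   "where": "mirnas:mir-429 ranking",
   "printed": -5,
   "computed": -6,
   "note": "published Ranking entry differs from the sum of its own printed row"
  }
 ]
}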