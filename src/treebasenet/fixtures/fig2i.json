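{
 "format": "treebase-net-v1",
 "name": "fig2i",
 "comment": "Not tree-based: the non-leaf antichain {u,v,w} is larger than the two-element leaf set, so the maximum-antichain screen applies.",
 "vertices": [
  {
   "id": "h"
  },
  {
   "id": "p"
  },
  {
   "id": "q"
  },
  {
   "id": "r"
  },
  {
   "id": "rho"
  },
  {
   "id": "s"
  },
  {
   "id": "u"
  },
  {
   "id": "v"
  },
  {
   "id": "w"
  },
  {
   "id": "x",
   "label": "x"
  },
  {
   "id": "y",
   "label": "y"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "p"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "s"
  },
  {
   "id": "e02",
   "source": "s",
   "target": "q"
  },
  {
   "id": "e03",
   "source": "s",
   "target": "r"
  },
  {
   "id": "e04",
   "source": "p",
   "target": "u"
  },
  {
   "id": "e05",
   "source": "p",
   "target": "v"
  },
  {
   "id": "e06",
   "source": "q",
   "target": "u"
  },
  {
   "id": "e07",
   "source": "q",
   "target": "w"
  },
  {
   "id": "e08",
   "source": "r",
   "target": "v"
  },
  {
   "id": "e09",
   "source": "r",
   "target": "w"
  },
  {
   "id": "e10",
   "source": "u",
   "target": "h"
  },
  {
   "id": "e11",
   "source": "v",
   "target": "h"
  },
  {
   "id": "e12",
   "source": "h",
   "target": "x"
  },
  {
   "id": "e13",
   "source": "w",
   "target": "y"
  }
 ]
}
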