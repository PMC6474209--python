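{
 "description": "Synthetic stand-in for the eight canonical 4-channel spatiotemporal stimulation patterns (illustrative event lists, not measured data).",
 "patterns": [
  {
   "label": "F5",
   "channel_pulses": [
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ],
    [
     32.0,
     36.0,
     40.0,
     192.0,
     196.0,
     200.0
    ],
    [
     44.0,
     48.0,
     52.0,
     204.0,
     208.0,
     212.0
    ],
    [
     56.0,
     60.0,
     64.0,
     216.0,
     220.0,
     224.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "S5",
   "channel_pulses": [
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ],
    [
     46.0,
     71.0,
     96.0,
     121.0,
     146.0,
     171.0,
     196.0,
     221.0,
     246.0,
     271.0,
     296.0
    ],
    [
     58.0,
     83.0,
     108.0,
     133.0,
     158.0,
     183.0,
     208.0,
     233.0,
     258.0,
     283.0,
     308.0
    ],
    [
     70.0,
     95.0,
     120.0,
     145.0,
     170.0,
     195.0,
     220.0,
     245.0,
     270.0,
     295.0,
     320.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "F10",
   "channel_pulses": [
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ],
    [
     28.0,
     32.0,
     36.0,
     188.0,
     192.0,
     196.0
    ],
    [
     36.0,
     40.0,
     44.0,
     196.0,
     200.0,
     204.0
    ],
    [
     44.0,
     48.0,
     52.0,
     204.0,
     208.0,
     212.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "S10",
   "channel_pulses": [
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ],
    [
     42.0,
     67.0,
     92.0,
     117.0,
     142.0,
     167.0,
     192.0,
     217.0,
     242.0,
     267.0,
     292.0
    ],
    [
     50.0,
     75.0,
     100.0,
     125.0,
     150.0,
     175.0,
     200.0,
     225.0,
     250.0,
     275.0,
     300.0
    ],
    [
     58.0,
     83.0,
     108.0,
     133.0,
     158.0,
     183.0,
     208.0,
     233.0,
     258.0,
     283.0,
     308.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "F20",
   "channel_pulses": [
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ],
    [
     24.0,
     28.0,
     32.0,
     184.0,
     188.0,
     192.0
    ],
    [
     28.0,
     32.0,
     36.0,
     188.0,
     192.0,
     196.0
    ],
    [
     32.0,
     36.0,
     40.0,
     192.0,
     196.0,
     200.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "S20",
   "channel_pulses": [
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ],
    [
     38.0,
     63.0,
     88.0,
     113.0,
     138.0,
     163.0,
     188.0,
     213.0,
     238.0,
     263.0,
     288.0
    ],
    [
     42.0,
     67.0,
     92.0,
     117.0,
     142.0,
     167.0,
     192.0,
     217.0,
     242.0,
     267.0,
     292.0
    ],
    [
     46.0,
     71.0,
     96.0,
     121.0,
     146.0,
     171.0,
     196.0,
     221.0,
     246.0,
     271.0,
     296.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "Finf",
   "channel_pulses": [
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ],
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ],
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ],
    [
     20.0,
     24.0,
     28.0,
     180.0,
     184.0,
     188.0
    ]
   ],
   "duration": 340.0
  },
  {
   "label": "Sinf",
   "channel_pulses": [
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ],
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ],
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ],
    [
     34.0,
     59.0,
     84.0,
     109.0,
     134.0,
     159.0,
     184.0,
     209.0,
     234.0,
     259.0,
     284.0
    ]
   ],
   "duration": 340.0
  }
 ]
}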