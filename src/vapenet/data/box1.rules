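# Theme-based classification rule set for e-cigarette-related video text.
#
# Format: "[class name]" starts a class section; each following non-blank,
# non-comment line is one indicator pattern.
#   - a single word       -> whole-lemma match
#   - several words       -> contiguous lemma phrase (quotes optional)
#   - terms joined by "+" -> conjunction: every term must occur somewhere
# The last class listed with no indicators is the fallback class.

[e-cigarette device]
e-cigarette
electronic cigarette
e-cig
ecig
vape pen
vapepen
vape
pod
pod mod
disposable ecig
disposable vape
disposable
cigalike
box mod
boxmod
juul
puff bar
cartomizer
drip
drip tip
vape kit
mod
electronic nicotine delivery system
ENDS
puffbar
sourin
blu
smok
leaf
markten
nicotek
vuse
fin
v2
21st
atomizer
RDA
RTA
cartridge
ohm
wattage
watt
ecig + device
vape + device

[e-liquid]
e-juice
e-liquid
ejuice
eliquid
vape juice
vape liquid
zamplebox

[cannabis vaping products]
cheeba
dab
firefly
ganja
gpen
hemp
indica
kush
marijuana
pax
pot
reefer
sativa
snoop dogg
weed
THC
cannabis
hash
wax
CBD

[other e-cigarette videos]
# Fallback: videos matching no indicator above land here.
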