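# Background vocabulary for synthetic transcripts: everyday content words,
# disjoint (after lemmatization) from every word used by any classifier
# indicator pattern; enforced by a regression test.
morning
afternoon
evening
window
garden
street
music
guitar
camera
travel
journey
mountain
valley
river
ocean
forest
island
bridge
castle
market
bakery
coffee
breakfast
dinner
recipe
kitchen
table
chair
carpet
ceiling
mirror
candle
blanket
pillow
jacket
sweater
pocket
button
ribbon
fabric
color
paint
brush
canvas
sketch
gallery
museum
library
novel
chapter
poem
story
author
reader
teacher
student
lesson
classroom
notebook
pencil
eraser
ruler
calendar
season
winter
summer
spring
autumn
weather
thunder
sunshine
rainbow
shadow
whisper
echo
melody
rhythm
chorus
violin
piano
trumpet
audience
theater
curtain
ticket
luggage
airport
station
railway
bicycle
engine
wheel
harbor
anchor
compass
lantern
meadow
orchard
harvest
basket
bottle
spoon
plate
napkin
saucer
kettle
oven
garlic
onion
pepper
tomato
carrot
potato
spinach
lettuce
apple
orange
banana
cherry
grape
lemon
melon
peach
walnut
almond
honey
butter
cheese
yogurt
cereal
noodle
salad
soup
sandwich
picnic
holiday
weekend
birthday
festival
parade
costume
lantern
firework
balloon
puzzle
riddle
marble
kite
swing
ladder
hammer
shovel
bucket
fence
gate
roof
chimney
cellar
attic
stair
hallway
corridor
balcony
terrace
fountain
statue
tower
clock
bell
drawer
shelf
cabinet
closet
pantry
porch
driveway
sidewalk
avenue
boulevard
tunnel
subway
ferry
sailboat
canoe
paddle
lighthouse
seagull
pelican
sparrow
robin
falcon
turtle
rabbit
squirrel
hedgehog
badger
otter
beaver
moose
antler
prairie
canyon
plateau
glacier
volcano
desert
oasis
lagoon
reef
tide
current
breeze
drizzle
frost
icicle
snowflake
puddle
pebble
boulder
cliff
summit
ridge
slope
trail
footpath
campfire
tent
backpack
thermos
binocular
telescope
microscope
magnet
circuit
spark
signal
antenna
satellite
rocket
planet
comet
meteor
galaxy
nebula
horizon
twilight
midnight
daybreak
noon
dusk
dawn
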